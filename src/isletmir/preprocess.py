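"""Ct censoring, detection filtering, dCt normalization and fold changes.

The quantification model is the standard comparative-Ct scheme: within each
sample, dCt = Ct(assay) - Ct(endogenous control); between paired cell types
of one donor, the per-donor difference z = dCt(alpha) - dCt(beta); the
relative quantity beta vs alpha is RQ = 2^-ddCt = 2^z.  Because the control
is subtracted within each sample, any per-sample additive shift in Ct (RNA
loading, control drift in either direction across preparations) cancels
exactly -- that invariance is what makes the paired design robust and is
tested as a property.

Censoring: Ct values above the instrument detection limit (32 cycles for
the array platform) are unreliable; they and undetected wells are set to
the limit itself, and the pre-censoring detection state is kept as a mask
for the detection filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from isletmir.io_ct import CtMatrix, CtIOError

#: Platform detection limit for the array cards, in cycles.
DEFAULT_CUTOFF_CT = 32.0
#: Single-assay qPCR "undetermined" threshold, in cycles.
DEFAULT_UNDETERMINED_CT = 35.0
#: Equal-expression fold-change band (beta vs alpha).
DEFAULT_EQUAL_BAND = (2.0 / 3.0, 1.5)

DETECTION_SCOPES = ("either", "both", "pooled")
FC_AGGREGATIONS = ("geometric", "arithmetic")


class PreprocessError(ValueError):
    """Invalid preprocessing input (missing control, unpaired donor, ...)."""


def censor_cts(m: CtMatrix, cutoff: float = DEFAULT_CUTOFF_CT) -> CtMatrix:
    """Censor Ct values at the detection limit.

    Every value above ``cutoff`` and every undetected well is replaced by
    ``cutoff``; values at or below are unchanged.  The returned matrix
    carries a ``detected`` mask recording, per well, whether the
    pre-censoring Ct was strictly below ``cutoff``.  Idempotent.
    """
    if cutoff <= 0:
        raise PreprocessError("cutoff must be positive cycles")
    out = m.copy()
    if m.detected is not None:
        # already censored: keep the original mask
        out.detected = m.detected.copy()
    else:
        out.detected = m.values.notna() & (m.values < cutoff)
    out.values = m.values.clip(upper=cutoff).fillna(cutoff)
    return out


def _detection_mask(m: CtMatrix, cutoff: float) -> pd.DataFrame:
    if m.detected is not None:
        return m.detected
    return m.values.notna() & (m.values < cutoff)


def detection_filter(
    m: CtMatrix,
    cutoff: float = DEFAULT_CUTOFF_CT,
    min_detected: int = 4,
    scope: str = "either",
) -> list[str]:
    """Assays reliably detected in enough donors; controls excluded.

    An assay counts as detected in a donor's cell-type population when its
    pre-censoring Ct is strictly below ``cutoff`` in that donor's sample
    (replicates: any detected sample counts).  ``scope`` resolves what
    "detected in >= min_detected of the donors" ranges over:

    - ``either`` (default): >= min_detected donors within the alpha
      population OR within the beta population.  A miRNA absent from
      alpha-cells but solidly expressed in beta-cells survives, which is
      required for cell-type-specific miRNAs.
    - ``both``: the threshold must hold in each population separately.
    - ``pooled``: a donor counts if the assay is detected in any of the
      donor's samples of either type.

    Returns the retained assay IDs in matrix order.
    """
    if scope not in DETECTION_SCOPES:
        raise PreprocessError(f"unknown detection scope {scope!r}")
    m.check_paired()
    n_donors = len(m.donor_ids)
    if min_detected > n_donors:
        raise PreprocessError(
            f"min_detected={min_detected} exceeds n_donors={n_donors}"
        )
    mask = _detection_mask(m, cutoff)
    # donors x assays counts per cell type: detected in >=1 sample of that type
    per_type = {}
    for ct in ("alpha", "beta"):
        cols = m.samples.index[m.samples["cell_type"] == ct]
        sub = mask[cols]
        donor_of = m.samples.loc[cols, "donor_id"]
        per_type[ct] = sub.T.groupby(donor_of).any().sum(axis=0)
    n_alpha, n_beta = per_type["alpha"], per_type["beta"]
    if scope == "either":
        keep = (n_alpha >= min_detected) | (n_beta >= min_detected)
    elif scope == "both":
        keep = (n_alpha >= min_detected) & (n_beta >= min_detected)
    else:  # pooled
        pooled = mask.T.groupby(m.samples["donor_id"]).any().sum(axis=0)
        keep = pooled >= min_detected
    return [a for a in m.assay_ids if keep[a] and a not in m.control_assays]


def delta_ct(m: CtMatrix, control: str = "RNU48") -> "DeltaCtMatrix":
    """Normalize each sample to its endogenous-control Ct.

    dCt[i, s] = Ct[i, s] - Ct[control, s].  The control must be flagged in
    ``control_assays`` and detected in every sample -- an undetected
    control makes normalization meaningless, so that is a hard error
    naming the sample.  All control rows are dropped from the output.
    """
    if control not in m.control_assays or control not in m.values.index:
        raise PreprocessError(f"control assay {control!r} absent from matrix")
    mask = _detection_mask(m, DEFAULT_CUTOFF_CT)
    ctrl_detected = mask.loc[control]
    if not ctrl_detected.all():
        bad = list(ctrl_detected.index[~ctrl_detected])
        raise PreprocessError(
            f"control {control!r} undetected in sample(s) {bad}"
        )
    ctrl = m.values.loc[control]
    values = m.values.sub(ctrl, axis=1)
    values = values.drop(index=[a for a in m.control_assays if a in values.index])
    return DeltaCtMatrix(values=values, samples=m.samples.copy(), control_used=control)


@dataclass
class DeltaCtMatrix:
    """Control-normalized dCt values (assays x samples, cycles)."""

    values: pd.DataFrame
    samples: pd.DataFrame
    control_used: str

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PairedDiffMatrix:
    """Per-donor paired differences z = dCt(alpha) - dCt(beta), in cycles.

    z > 0 means the miRNA is relatively less abundant in alpha-cells,
    i.e. beta-enriched.
    """

    values: pd.DataFrame  # assays x donors
    control_used: str

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def donor_ids(self) -> list[str]:
        return list(self.values.columns)


def paired_differences(d: DeltaCtMatrix) -> PairedDiffMatrix:
    """Collapse samples to per-donor paired differences.

    Within-donor technical replicates (several samples of one cell type)
    are averaged on the dCt scale first; every donor must then contribute
    exactly one alpha and one beta profile.
    """
    by = d.samples.groupby(["donor_id", "cell_type"]).groups
    donors = list(dict.fromkeys(d.samples["donor_id"]))
    cols = {}
    for donor in donors:
        try:
            alpha_cols = by[(donor, "alpha")]
            beta_cols = by[(donor, "beta")]
        except KeyError:
            raise PreprocessError(f"donor {donor!r} lacks an alpha/beta pair")
        alpha = d.values[list(alpha_cols)].mean(axis=1)
        beta = d.values[list(beta_cols)].mean(axis=1)
        cols[donor] = alpha - beta
    z = pd.DataFrame(cols, index=d.values.index)
    return PairedDiffMatrix(values=z, control_used=d.control_used)


def fold_change(
    z: PairedDiffMatrix,
    equal_band: tuple[float, float] = DEFAULT_EQUAL_BAND,
    aggregation: str = "geometric",
) -> pd.DataFrame:
    """Per-miRNA beta-vs-alpha fold change with an enrichment category.

    ``geometric`` (default) aggregates on the Ct scale, FC = 2^mean(z) --
    the relative quantity 2^-ddCt applied to the donor-averaged ddCt, as
    qPCR analysis software conventionally does.  ``arithmetic`` averages
    the per-donor relative quantities 2^z instead.

    Category: ``equal`` when FC falls inside ``equal_band`` (closed),
    ``beta_enriched`` strictly above, ``alpha_enriched`` strictly below.
    ``fc_reported`` restates FC in the direction of enrichment (the
    reciprocal for alpha-enriched miRNAs), matching how fold changes are
    quoted per direction in result tables.
    """
    if aggregation not in FC_AGGREGATIONS:
        raise PreprocessError(f"unknown fc aggregation {aggregation!r}")
    lo, hi = equal_band
    if not (0 < lo <= 1 <= hi):
        raise PreprocessError("equal_band must bracket 1")
    vals = z.values.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise PreprocessError("paired differences contain non-finite values")
    if aggregation == "geometric":
        fc = np.exp2(vals.mean(axis=1))
    else:
        fc = np.exp2(vals).mean(axis=1)
    category = np.where(
        fc > hi, "beta_enriched", np.where(fc < lo, "alpha_enriched", "equal")
    )
    reported = np.where(category == "alpha_enriched", 1.0 / fc, fc)
    return pd.DataFrame(
        {
            "mirna": z.assay_ids,
            "fc_beta_vs_alpha": fc,
            "fc_reported": reported,
            "category": category,
        }
    )


def single_assay_rq(
    ct_gene: float,
    ct_control: float,
    undetermined_cutoff: float = DEFAULT_UNDETERMINED_CT,
) -> float | None:
    """Relative quantity for a single follow-up qPCR assay.

    RQ = 2^-(Ct_gene - Ct_control); a gene Ct at or beyond the
    ``undetermined_cutoff`` (35 cycles) is reported as undetermined
    (``None``) rather than quantified.
    """
    if ct_gene >= undetermined_cutoff:
        return None
    return float(2.0 ** -(ct_gene - ct_control))
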