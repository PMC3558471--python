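"""Synthetic Ct matrices, prediction databases and gene groups with truth.

The generator emulates the statistical structure of a paired two-cell-type
TLDA profiling study: a ~667-assay panel over 6 donors, each donor
contributing one alpha and one beta sample.  The noise model is

    Ct[i, donor, type] = baseline_i  - effect_i * [type is enriched]
                         + donor_noise[i, donor]      (shared in the pair)
                         + drift[sample]              (all assays incl. control)
                         + well_noise                 (independent per well)

* ``effect_i`` is the planted log2 beta-vs-alpha enrichment in cycles
  (positive = beta-enriched); the enriched cell type's Ct drops by
  |effect_i| while the other cell type stays at baseline.
* donor noise is shared within a donor's alpha/beta pair -- the
  preparation-level variation that the paired design cancels and the
  reason a one-class analysis of paired differences is the right test.
* the per-sample drift models endogenous-control abundance varying in
  both directions across preparations; because it shifts every assay of
  a sample including the control, dCt normalization removes it exactly.
* wells whose Ct lands above the detection limit are emitted as
  undetected, so strong beta-enrichment naturally produces miRNAs that
  drop out of the alpha samples -- the regime the detection filter and
  censoring rules exist for.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from isletmir.io_ct import CtMatrix
from isletmir.targets import GeneGroupSet, PredictionDB, GROUP_NAMES

CATEGORIES = ("beta_enriched", "alpha_enriched", "equal", "null")


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-shaped simulation settings.

    Defaults mirror the profiled study: a 667-assay panel, 6 donors,
    roughly a fifth of the panel beta-enriched with effects of 1-7 cycles
    (fold changes 2-128, the span seen in practice), a handful of
    alpha-enriched and near-equal miRNAs, detection limit 32 cycles.
    ``donor_sd``/``assay_sd`` of 0.5/0.25 cycles are typical preparation
    and well-level qPCR variability for preamplified array cards.
    """

    n_mirnas: int = 667
    n_donors: int = 6
    frac_beta_enriched: float = 0.20
    frac_alpha_enriched: float = 0.01
    frac_equal: float = 0.05
    #: planted |effect| in cycles: a constant, or ("uniform", lo, hi)
    effect_log2: float | tuple = ("uniform", 1.0, 7.0)
    #: max |effect| for the "equal" category (inside the 2/3..3/2 band)
    equal_effect_max: float = 0.5
    donor_sd: float = 0.5
    assay_sd: float = 0.25
    baseline_ct_range: tuple[float, float] = (20.0, 31.0)
    control_drift_sd: float = 1.0
    censor_ct: float = 32.0
    undetected_fraction: float = 0.0
    control_assay: str = "RNU48"
    control_baseline_ct: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_beta_enriched, self.frac_alpha_enriched, self.frac_equal)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise SimError("category fractions must be in [0,1] and sum to <= 1")
        for sd in (self.donor_sd, self.assay_sd, self.control_drift_sd):
            if sd < 0:
                raise SimError("standard deviations must be non-negative")


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset."""

    mirnas: pd.DataFrame  # index mirna: true_category, true_effect_cycles
    planted_targets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mirna", "gene", "group"])
    )

    def enriched_ids(self) -> list[str]:
        cat = self.mirnas["true_category"]
        return list(self.mirnas.index[cat.isin(["beta_enriched", "alpha_enriched"])])


def _draw_effect(rng: np.random.Generator, spec, size: int) -> np.ndarray:
    if isinstance(spec, (int, float)):
        return np.full(size, float(spec))
    kind, lo, hi = spec
    if kind != "uniform":
        raise SimError(f"unknown effect distribution {kind!r}")
    return rng.uniform(lo, hi, size)


def simulate_ct_matrix(cfg: SimConfig) -> tuple[CtMatrix, TruthTable]:
    """Draw one study-shaped Ct matrix and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.n_mirnas, cfg.n_donors
    names = [f"sim-mir-{i + 1:04d}" for i in range(m)]

    n_beta = round(cfg.frac_beta_enriched * m)
    n_alpha = round(cfg.frac_alpha_enriched * m)
    n_equal = round(cfg.frac_equal * m)
    cats = np.array(
        ["beta_enriched"] * n_beta
        + ["alpha_enriched"] * n_alpha
        + ["equal"] * n_equal
        + ["null"] * (m - n_beta - n_alpha - n_equal)
    )
    rng.shuffle(cats)

    effect = np.zeros(m)
    effect[cats == "beta_enriched"] = _draw_effect(rng, cfg.effect_log2, n_beta)
    effect[cats == "alpha_enriched"] = -_draw_effect(rng, cfg.effect_log2, n_alpha)
    effect[cats == "equal"] = rng.uniform(
        -cfg.equal_effect_max, cfg.equal_effect_max, n_equal
    )

    lo, hi = cfg.baseline_ct_range
    baseline = rng.uniform(lo, hi, m)
    donor_noise = rng.normal(0.0, cfg.donor_sd, (m, n))
    drift = rng.normal(0.0, cfg.control_drift_sd, 2 * n)  # alpha block then beta

    donors = [f"D{j + 1}" for j in range(n)]
    sample_ids = [f"{d}_alpha" for d in donors] + [f"{d}_beta" for d in donors]
    ct = np.empty((m, 2 * n))
    # the enriched cell type's Ct drops by |effect|; the other stays at baseline,
    # so z = Ct_alpha - Ct_beta = effect after dCt normalization
    for j in range(n):
        base_j = baseline + donor_noise[:, j]
        ct[:, j] = base_j + np.minimum(effect, 0.0) + drift[j]
        ct[:, n + j] = base_j - np.maximum(effect, 0.0) + drift[n + j]
    ct += rng.normal(0.0, cfg.assay_sd, ct.shape)

    undetected = ct > cfg.censor_ct
    if cfg.undetected_fraction > 0:
        undetected |= rng.random(ct.shape) < cfg.undetected_fraction
    ct[undetected] = np.nan

    # the control carries exactly the per-sample drift: its own well noise
    # would propagate into every dCt of that sample as a shared shift,
    # correlating all features -- not the regime this generator emulates
    ctrl = cfg.control_baseline_ct + drift
    values = pd.DataFrame(
        np.vstack([ct, ctrl]), index=names + [cfg.control_assay], columns=sample_ids
    )
    samples = pd.DataFrame(
        {
            "donor_id": donors + donors,
            "cell_type": ["alpha"] * n + ["beta"] * n,
            "card": ["merged"] * 2 * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = CtMatrix(
        values=values, samples=samples, control_assays=frozenset({cfg.control_assay})
    )
    truth = TruthTable(
        mirnas=pd.DataFrame(
            {"true_category": cats, "true_effect_cycles": effect},
            index=pd.Index(names, name="mirna"),
        )
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# prediction databases and gene groups


@dataclass
class DbSimConfig:
    """Settings for planting target predictions around a truth table.

    Planted (miRNA, gene, group) triples go into ``plant_in_sources`` of
    the three databases; decoy pairs (random miRNA x gene, genes outside
    every group) and decoy group members add realistic clutter.
    """

    n_planted_mirnas: int = 10
    genes_per_mirna: int = 2
    plant_in_sources: int = 3  # 1..3
    n_decoy_pairs: int = 100
    decoy_genes_per_group: int = 10
    min_effect_for_plant: float = 1.6  # cycles; > log2(3), survives the FC>3 filter
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.plant_in_sources <= 3:
            raise SimError("plant_in_sources must be 1..3")


DB_SOURCES = ("pictar4way", "targetscan_conserved", "microcosm_v5")


def simulate_prediction_dbs(
    truth: TruthTable, cfg: DbSimConfig | None = None
) -> tuple[dict[str, PredictionDB], GeneGroupSet, TruthTable]:
    """Plant target predictions for beta-enriched miRNAs; return the three
    databases, the gene groups, and the truth table with its
    ``planted_targets`` filled in."""
    cfg = cfg or DbSimConfig()
    rng = np.random.default_rng(cfg.seed)

    strong_beta = truth.mirnas.index[
        (truth.mirnas["true_category"] == "beta_enriched")
        & (truth.mirnas["true_effect_cycles"] > cfg.min_effect_for_plant)
    ].tolist()
    n_plant = min(cfg.n_planted_mirnas, len(strong_beta))
    planted_mirnas = list(rng.choice(strong_beta, size=n_plant, replace=False))

    mapping: dict[str, dict[str, set[str]]] = {s: {} for s in DB_SOURCES}
    groups: dict[str, set[str]] = {g: set() for g in GROUP_NAMES}
    planted_rows = []
    gene_counter = 0
    for mirna in planted_mirnas:
        for _ in range(cfg.genes_per_mirna):
            gene_counter += 1
            gene = f"SIMGENE{gene_counter:04d}"
            group = GROUP_NAMES[int(rng.integers(len(GROUP_NAMES)))]
            groups[group].add(gene)
            sources = rng.choice(
                len(DB_SOURCES), size=cfg.plant_in_sources, replace=False
            )
            for s in sources:
                mapping[DB_SOURCES[s]].setdefault(mirna, set()).add(gene)
            planted_rows.append((mirna, gene, group))

    # decoys: genes outside every group, random miRNA attachments
    all_mirnas = truth.mirnas.index.tolist()
    for k in range(cfg.n_decoy_pairs):
        mirna = all_mirnas[int(rng.integers(len(all_mirnas)))]
        gene = f"DECOY{k:04d}"
        source = DB_SOURCES[int(rng.integers(len(DB_SOURCES)))]
        mapping[source].setdefault(mirna, set()).add(gene)
    for g in GROUP_NAMES:
        for k in range(cfg.decoy_genes_per_group):
            groups[g].add(f"GRPDECOY_{g}_{k:03d}")

    dbs = {s: PredictionDB(source=s, mapping=mapping[s]) for s in DB_SOURCES}
    planted = pd.DataFrame(planted_rows, columns=["mirna", "gene", "group"])
    return dbs, GeneGroupSet(groups=groups), replace(truth, planted_targets=planted)


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_metrics(
    sam_table: pd.DataFrame, truth: TruthTable
) -> tuple[float, float, float]:
    """(sensitivity, false-discovery proportion, direction accuracy).

    * sensitivity: recovered truly-enriched miRNAs over all truly enriched;
    * FDP: calls whose true category is ``null`` over all calls (a call on
      an ``equal``-category miRNA has a real, if small, effect and counts
      in neither numerator);
    * direction accuracy: among recovered truly-enriched miRNAs, the
      fraction whose called direction matches the planted one.
    Empty call sets score sensitivity 0 and FDP 0 by convention.
    """
    truth_cat = truth.mirnas["true_category"]
    enriched = set(truth.mirnas.index[truth_cat.isin(["beta_enriched", "alpha_enriched"])])
    calls = sam_table["mirna"].tolist()
    called_set = set(calls)
    if len(called_set) != len(calls):
        raise SimError("duplicate miRNAs in SAM table")
    unknown = called_set - set(truth.mirnas.index)
    if unknown:
        raise SimError(f"called miRNAs absent from truth: {sorted(unknown)}")

    tp = called_set & enriched
    false_calls = {m for m in called_set if truth_cat[m] == "null"}
    sensitivity = len(tp) / len(enriched) if enriched else 1.0
    fdp = len(false_calls) / max(1, len(called_set))
    if tp:
        dir_of = dict(zip(sam_table["mirna"], sam_table["direction"]))
        expected = {"beta_enriched": "beta", "alpha_enriched": "alpha"}
        good = sum(1 for m in tp if dir_of[m] == expected[truth_cat[m]])
        direction_acc = good / len(tp)
    else:
        direction_acc = 1.0
    return sensitivity, fdp, direction_acc
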