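"""Reading, validating and writing threshold-cycle (Ct) tables.

On-disk formats are plain tab-delimited UTF-8 text with ``.`` decimals:

``simple_tsv`` Ct matrix
    Row 1: ``assay_id`` followed by one column per sample ID.  One row per
    assay.  Cells are Ct values in cycles; undetected wells are written as
    ``Undetermined`` (the instrument's wording) or left empty.  A sidecar
    metadata TSV with columns ``sample_id, donor_id, cell_type, card``
    supplies the design (cell_type in {alpha, beta}; card in {A, B, merged}).

``tlda_export`` Ct table
    Long-format instrument-style export with columns (case-insensitive
    header match) ``Sample``, ``Detector`` (or ``Target``/``Assay``) and
    ``Ct``; the same sidecar metadata TSV is required.

Undetected wells are represented in memory by NaN -- a marker distinct from
any numeric Ct.  Nothing in this module imputes or censors; the censoring
policy is applied explicitly in :mod:`isletmir.preprocess`.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CELL_TYPES = ("alpha", "beta")
CARDS = ("A", "B", "merged")

#: Cell contents treated as the undetected marker when parsing (case-insensitive).
UNDETECTED_TOKENS = frozenset({"", "undetermined", "undet", "na", "n/a", "nan"})


class CtIOError(ValueError):
    """Malformed Ct table, metadata or result file."""


@dataclass
class CtMatrix:
    """Assays x samples threshold-cycle matrix with sample metadata.

    Attributes
    ----------
    values
        DataFrame indexed by assay_id, one column per sample_id; Ct in
        cycles, NaN = undetected.
    samples
        DataFrame indexed by sample_id with columns ``donor_id``,
        ``cell_type`` and ``card``, in the same order as ``values.columns``.
    control_assays
        Endogenous-control assay names (subset of the assay index).
    detected
        Optional boolean mask of the same shape as ``values`` recording
        which wells were detected *before* censoring (set by
        :func:`isletmir.preprocess.censor_cts`).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    control_assays: frozenset = field(default_factory=frozenset)
    detected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.control_assays = frozenset(self.control_assays)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        v, s = self.values, self.samples
        if list(v.columns) != list(s.index):
            raise CtIOError("sample columns of values do not match metadata rows")
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise CtIOError(f"duplicate assay IDs: {dups}")
        if s.index.duplicated().any():
            dups = s.index[s.index.duplicated()].unique().tolist()
            raise CtIOError(f"duplicate sample IDs: {dups}")
        missing_cols = {"donor_id", "cell_type", "card"} - set(s.columns)
        if missing_cols:
            raise CtIOError(f"sample metadata lacks columns: {sorted(missing_cols)}")
        bad_ct = set(s["cell_type"]) - set(CELL_TYPES)
        if bad_ct:
            raise CtIOError(f"unknown cell_type values: {sorted(bad_ct)}")
        bad_card = set(s["card"]) - set(CARDS)
        if bad_card:
            raise CtIOError(f"unknown card values: {sorted(bad_card)}")
        unknown_ctrl = self.control_assays - set(v.index)
        if unknown_ctrl:
            raise CtIOError(f"control assays not in matrix: {sorted(unknown_ctrl)}")
        finite = v.to_numpy(dtype=float)
        finite = finite[np.isfinite(finite)]
        if finite.size and (finite <= 0).any():
            raise CtIOError("Ct values must be positive cycles")
        if self.detected is not None:
            if self.detected.shape != v.shape:
                raise CtIOError("detected mask shape differs from values")

    # -- convenience --------------------------------------------------------
    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def donor_ids(self) -> list[str]:
        return list(dict.fromkeys(self.samples["donor_id"]))

    def mirna_assays(self) -> list[str]:
        """Assay IDs that are not endogenous controls."""
        return [a for a in self.values.index if a not in self.control_assays]

    def copy(self) -> "CtMatrix":
        return replace(
            self,
            values=self.values.copy(),
            samples=self.samples.copy(),
            detected=None if self.detected is None else self.detected.copy(),
        )

    def check_paired(self) -> None:
        """Raise unless every donor has at least one alpha and one beta sample."""
        counts = self.samples.groupby(["donor_id", "cell_type"]).size()
        for donor in self.donor_ids:
            for ct in CELL_TYPES:
                if counts.get((donor, ct), 0) < 1:
                    raise CtIOError(
                        f"donor {donor!r} has no {ct} sample; paired design invalid"
                    )


# ---------------------------------------------------------------------------
# parsing


def _parse_ct_cell(raw: object) -> float:
    if isinstance(raw, float):
        return raw
    text = str(raw).strip()
    if text.lower() in UNDETECTED_TOKENS:
        return math.nan
    try:
        return float(text)
    except ValueError as exc:
        raise CtIOError(f"unparseable Ct cell {text!r}") from exc


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sidecar metadata TSV (sample_id, donor_id, cell_type, card)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "donor_id", "cell_type", "card"}
    missing = required - set(meta.columns)
    if missing:
        raise CtIOError(f"metadata file lacks columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")[["donor_id", "cell_type", "card"]]
    return meta


def read_ct_table(
    path,
    metadata,
    dialect: str = "simple_tsv",
    control_assays=("RNU48",),
) -> CtMatrix:
    """Read a Ct table plus sample metadata into a :class:`CtMatrix`.

    Parameters
    ----------
    path
        Ct table file in the given dialect.
    metadata
        Path to the sidecar metadata TSV, or an already-parsed DataFrame
        indexed by sample_id.
    dialect
        ``simple_tsv`` (wide, assays x samples) or ``tlda_export`` (long).
    control_assays
        Names flagged as endogenous controls if present in the table.

    A sample in the Ct table that has no metadata row is a hard error
    naming the sample; assay and sample order are preserved from the file.
    """
    if dialect == "simple_tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        values = raw.map(_parse_ct_cell).astype(float)
    elif dialect == "tlda_export":
        values = _read_tlda_long(path)
    else:
        raise CtIOError(f"unknown Ct dialect {dialect!r}")

    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)

    meta = metadata if isinstance(metadata, pd.DataFrame) else read_sample_metadata(metadata)
    for sample in values.columns:
        if sample not in meta.index:
            raise CtIOError(f"sample {sample!r} has no metadata row")
        if pd.isna(meta.loc[sample]).any():
            raise CtIOError(f"sample {sample!r} has incomplete metadata")
    meta = meta.loc[list(values.columns)]

    controls = frozenset(a for a in control_assays if a in values.index)
    return CtMatrix(values=values, samples=meta, control_assays=controls)


def _read_tlda_long(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower().strip(): c for c in table.columns}
    sample_col = cols.get("sample") or cols.get("sample name")
    assay_col = cols.get("detector") or cols.get("target") or cols.get("assay")
    ct_col = cols.get("ct")
    if not (sample_col and assay_col and ct_col):
        raise CtIOError(
            "tlda_export needs columns Sample, Detector/Target/Assay and Ct"
        )
    dup = table.duplicated(subset=[sample_col, assay_col])
    if dup.any():
        first = table.loc[dup, assay_col].iloc[0]
        raise CtIOError(f"duplicate assay {first!r} for one sample in export")
    long = table[[assay_col, sample_col, ct_col]].copy()
    long[ct_col] = long[ct_col].map(_parse_ct_cell)
    wide = long.pivot(index=assay_col, columns=sample_col, values=ct_col)
    # preserve first-appearance order from the export
    assay_order = list(dict.fromkeys(table[assay_col]))
    sample_order = list(dict.fromkeys(table[sample_col]))
    wide = wide.loc[assay_order, sample_order]
    wide.index.name = "assay_id"
    wide.columns.name = None
    return wide.astype(float)


# ---------------------------------------------------------------------------
# writing (round-trip safe)


def write_ct_table(m: CtMatrix, ct_path, metadata_path) -> None:
    """Write a CtMatrix in simple_tsv + sidecar metadata form.

    ``read_ct_table(write_ct_table(m))`` reproduces ``m`` exactly (undetected
    cells round-trip through the ``Undetermined`` token).
    """
    out = m.values.copy()
    out.index.name = "assay_id"
    text = out.to_csv(sep="\t", na_rep="Undetermined")
    with open(ct_path, "w", encoding="utf-8") as fh:
        fh.write(text)
    meta = m.samples.reset_index()
    if meta.columns[0] != "sample_id":
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta.to_csv(metadata_path, sep="\t", index=False)


def merge_cards(a: CtMatrix, b: CtMatrix) -> CtMatrix:
    """Merge two card-level Ct matrices into one whole-panel matrix.

    Samples are matched by ``(donor_id, cell_type)``; a sample present on
    only one card is a hard error.  Assay sets must be disjoint except for
    shared control assays, which are retained once per card with a
    card-suffixed name (e.g. ``RNU48_A``) so that control choice remains a
    downstream decision rather than being silently averaged here.
    """
    card_a = _single_card_label(a)
    card_b = _single_card_label(b)

    key_a = {(r.donor_id, r.cell_type): s for s, r in a.samples.iterrows()}
    key_b = {(r.donor_id, r.cell_type): s for s, r in b.samples.iterrows()}
    only_a = set(key_a) - set(key_b)
    only_b = set(key_b) - set(key_a)
    if only_a or only_b:
        missing = sorted(only_a | only_b)
        raise CtIOError(f"samples present on only one card: {missing}")

    shared = set(a.assay_ids) & set(b.assay_ids)
    non_ctrl_shared = shared - (a.control_assays & b.control_assays)
    if non_ctrl_shared:
        raise CtIOError(
            f"non-control assays shared between cards: {sorted(non_ctrl_shared)}"
        )

    def suffix(m: CtMatrix, card: str) -> tuple[pd.DataFrame, set]:
        renames = {c: f"{c}_{card}" for c in m.control_assays & shared}
        ctrls = {renames.get(c, c) for c in m.control_assays}
        return m.values.rename(index=renames), ctrls

    va, ctrl_a = suffix(a, card_a)
    vb, ctrl_b = suffix(b, card_b)
    # align b's columns to a's sample order via the (donor, cell_type) key
    order_b = [key_b[(r.donor_id, r.cell_type)] for _, r in a.samples.iterrows()]
    vb = vb[order_b]
    vb.columns = va.columns

    values = pd.concat([va, vb], axis=0)
    samples = a.samples.copy()
    samples["card"] = "merged"
    return CtMatrix(
        values=values,
        samples=samples,
        control_assays=frozenset(ctrl_a | ctrl_b),
    )


def _single_card_label(m: CtMatrix) -> str:
    labels = set(m.samples["card"])
    if len(labels) != 1:
        raise CtIOError(f"matrix mixes card labels {sorted(labels)}")
    return labels.pop()


# ---------------------------------------------------------------------------
# result tables

SAM_TABLE_COLUMNS = ["mirna", "score_d", "q_percent", "fold_change", "direction"]
GLOBAL_TABLE_COLUMNS = ["mirna", "fc_beta_vs_alpha", "fc_reported", "category"]
TARGET_REPORT_COLUMNS = ["mirna", "group", "source", "gene", "consensus"]


def _direction_rank(direction: pd.Series) -> pd.Series:
    return direction.map({"beta": 0, "alpha": 1})


def sort_sam_table(t: pd.DataFrame) -> pd.DataFrame:
    """Deterministic presentation order: beta before alpha, descending fold
    change within a direction, assay name as final tie-break."""
    t = t.copy()
    t["_dir"] = _direction_rank(t["direction"])
    t = t.sort_values(
        ["_dir", "fold_change", "mirna"], ascending=[True, False, True]
    ).drop(columns="_dir")
    return t.reset_index(drop=True)


def write_sam_table(t: pd.DataFrame, path) -> None:
    """Write a significant-miRNA table (columns mirna, score_d, q_percent,
    fold_change, direction), sorted in presentation order."""
    if t.empty:
        raise CtIOError("refusing to write an empty result table")
    missing = set(SAM_TABLE_COLUMNS) - set(t.columns)
    if missing:
        raise CtIOError(f"SAM table lacks columns: {sorted(missing)}")
    sort_sam_table(t[SAM_TABLE_COLUMNS]).to_csv(path, sep="\t", index=False)


def read_sam_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"mirna": str, "direction": str})
    missing = set(SAM_TABLE_COLUMNS) - set(t.columns)
    if missing:
        raise CtIOError(f"SAM table lacks columns: {sorted(missing)}")
    return t


def write_global_table(t: pd.DataFrame, path) -> None:
    """Write the all-detected-miRNA fold-change table."""
    if t.empty:
        raise CtIOError("refusing to write an empty result table")
    missing = set(GLOBAL_TABLE_COLUMNS) - set(t.columns)
    if missing:
        raise CtIOError(f"global FC table lacks columns: {sorted(missing)}")
    out = t[GLOBAL_TABLE_COLUMNS].sort_values(
        ["fc_beta_vs_alpha", "mirna"], ascending=[False, True]
    )
    out.to_csv(path, sep="\t", index=False)


def read_global_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"mirna": str, "category": str})
    missing = set(GLOBAL_TABLE_COLUMNS) - set(t.columns)
    if missing:
        raise CtIOError(f"global FC table lacks columns: {sorted(missing)}")
    return t


def write_target_report(rows: pd.DataFrame, path) -> None:
    """Write the target-intersection report (one row per mirna/group/source/gene)."""
    if rows.empty:
        raise CtIOError("refusing to write an empty result table")
    missing = set(TARGET_REPORT_COLUMNS) - set(rows.columns)
    if missing:
        raise CtIOError(f"target report lacks columns: {sorted(missing)}")
    out = rows[TARGET_REPORT_COLUMNS].sort_values(
        ["mirna", "group", "source", "gene"]
    )
    out.to_csv(path, sep="\t", index=False)


def read_target_report(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype=str)
    t["consensus"] = t["consensus"].astype(int)
    return t


# ---------------------------------------------------------------------------
# optional GEO series-matrix adapter


def read_series_matrix(path, control_assays=("RNU48",)) -> CtMatrix:
    """Thin adapter for an already-downloaded GEO series-matrix text file.

    Reads the ``!series_matrix_table_begin``..``end`` block as the Ct
    matrix and derives donor/cell-type metadata from ``!Sample_title``
    lines of the form ``<celltype> <donor>`` (e.g. ``alpha D1``).  This is
    a convenience for re-analysing a deposited series; it performs no
    network access.
    """
    titles: list[str] = []
    table_lines: list[str] = []
    in_table = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!Sample_title"):
                titles = [t.strip().strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!series_matrix_table_begin"):
                in_table = True
            elif line.startswith("!series_matrix_table_end"):
                in_table = False
            elif in_table:
                table_lines.append(line)
    if not table_lines:
        raise CtIOError("no series-matrix table block found")
    raw = pd.read_csv(
        io.StringIO("\n".join(table_lines)), sep="\t", index_col=0, dtype=str
    )
    raw.index = [str(i).strip('"') for i in raw.index]
    raw.columns = [str(c).strip('"') for c in raw.columns]
    values = raw.map(_parse_ct_cell).astype(float)

    meta_rows = []
    if len(titles) != len(values.columns):
        raise CtIOError("sample titles do not match table columns")
    for sample, title in zip(values.columns, titles):
        parts = title.split()
        cell_type = next((p for p in parts if p.lower() in CELL_TYPES), None)
        donor = next((p for p in parts if p.lower() not in CELL_TYPES), None)
        if cell_type is None or donor is None:
            raise CtIOError(f"cannot parse cell type/donor from title {title!r}")
        meta_rows.append((sample, donor, cell_type.lower(), "merged"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "donor_id", "cell_type", "card"]
    ).set_index("sample_id")
    controls = frozenset(a for a in control_assays if a in values.index)
    return CtMatrix(values=values, samples=meta, control_assays=controls)
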