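"""Intersection of enriched-miRNA target predictions with islet gene groups.

Three public prediction resources are supported, each as a delimited-text
dialect (column positions documented on :func:`read_predictions`), plus a
``generic`` three-column form.  miRNA identifiers from array assay names
and from the databases follow different nomenclatures; both sides are
passed through :func:`normalize_mirna_id` before joining, with an optional
user-editable alias table for the remainder.

The report lists, for every miRNA of interest and every database, the
predicted targets that fall in each islet gene group (alpha-enriched
genes aG, beta-enriched genes bG, and the shared/alpha/beta transcription
factor groups abTF/aTF/bTF), and a consensus count of how many databases
predict each (miRNA, gene) pair.  Consensus is informational; by default
a single supporting database suffices, mirroring a per-algorithm report.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

GROUP_NAMES = ("aG", "bG", "abTF", "aTF", "bTF")
DB_DIALECTS = ("generic", "pictar4way", "targetscan_conserved", "microcosm_v5")


class TargetError(ValueError):
    pass


@dataclass
class PredictionDB:
    """miRNA -> target-gene mapping from one prediction source."""

    source: str
    mapping: dict[str, set[str]]
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def targets_of(self, mirna: str) -> set[str]:
        return self.mapping.get(mirna, set())

    @property
    def n_pairs(self) -> int:
        return sum(len(g) for g in self.mapping.values())


@dataclass
class GeneGroupSet:
    """The five islet gene groups used for intersection."""

    groups: dict[str, set[str]]

    def __post_init__(self) -> None:
        if set(self.groups) != set(GROUP_NAMES):
            raise TargetError(
                f"gene groups must be exactly {GROUP_NAMES}, got {sorted(self.groups)}"
            )


@dataclass
class TargetReport:
    """Intersection result: long rows plus per-miRNA summary counts."""

    rows: pd.DataFrame  # mirna, group, source, gene, consensus
    summary: pd.DataFrame  # mirna, group, source, n_targets
    unmatched: list[str]  # miRNAs absent from every database


# ---------------------------------------------------------------------------
# identifier normalization

_MIRNA_RE = re.compile(
    r"^(?:(?P<sp>[a-z]{3})-)?(?P<fam>mir|let|miR|Let|MIR|LET|MiR)-?(?P<rest>\S+)$",
    re.IGNORECASE,
)


def normalize_mirna_id(
    raw: str,
    species_prefix: str = "hsa",
    aliases: dict[str, str] | None = None,
) -> str:
    """Canonicalize a miRNA identifier for cross-database joining.

    Lower-cases, strips the species prefix, and normalizes the family stem
    to ``mir``/``let``; the star (``*``) and ``-3p``/``-5p`` suffixes are
    meaningful (they name distinct mature strands) and are preserved
    verbatim.  An alias table, applied last, absorbs residual nomenclature
    differences.  Idempotent.  An identifier that does not look like a
    miRNA name passes through lower-cased with a warning, never dropped.
    """
    if not raw or not str(raw).strip():
        raise TargetError("empty miRNA identifier")
    text = str(raw).strip()
    match = _MIRNA_RE.match(text)
    if match is None:
        warnings.warn(f"unrecognized miRNA identifier {text!r}; passing through")
        canon = text.lower()
    else:
        sp = (match.group("sp") or "").lower()
        if sp and sp != species_prefix.lower():
            # foreign species prefix: keep it, so ids never collide silently
            stem = f"{sp}-"
        else:
            stem = ""
        fam = "let" if match.group("fam").lower().startswith("let") else "mir"
        canon = f"{stem}{fam}-{match.group('rest').lower()}"
    if aliases:
        canon = aliases.get(canon, canon)
    return canon


def read_alias_table(path) -> dict[str, str]:
    """Two-column TSV (from_id, to_id); '#' comments allowed."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if table.shape[1] < 2:
        raise TargetError("alias table needs two columns")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


# ---------------------------------------------------------------------------
# prediction databases

#: Column positions per dialect: (mirna, gene_symbol, score or None).
_DIALECT_COLUMNS = {
    "generic": (0, 1, 2),
    # PicTar 4-way export: mirna, transcript, gene symbol, pictar score
    "pictar4way": (0, 2, 3),
    # TargetScan conserved-site summary: mirna family/member, gene id,
    # gene symbol, species, aggregate score
    "targetscan_conserved": (0, 2, 4),
    # microcosm v5 target download: GROUP SEQ METHOD FEATURE CHR START END
    # STRAND PHASE SCORE PVALUE TRANSCRIPT EXTERNAL_NAME
    "microcosm_v5": (1, 12, 9),
}


def read_predictions(
    path,
    dialect: str = "generic",
    source: str | None = None,
    species_prefix: str = "hsa",
    aliases: dict[str, str] | None = None,
    max_malformed_fraction: float = 0.10,
) -> PredictionDB:
    """Read a miRNA->gene prediction table in one of the known dialects.

    Lines starting with ``#`` and a single header line (detected by a
    non-numeric score field on dialects that carry one) are skipped.
    Malformed lines are logged and skipped; more than
    ``max_malformed_fraction`` of them is a hard error.  Duplicate
    (miRNA, gene) pairs collapse to the best (highest) score.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise TargetError(f"unknown prediction dialect {dialect!r}")
    mi_col, gene_col, score_col = _DIALECT_COLUMNS[dialect]
    source = source or dialect

    mapping: dict[str, set[str]] = {}
    scores: dict[tuple[str, str], float] = {}
    n_lines = n_bad = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            n_lines += 1
            try:
                mirna = normalize_mirna_id(
                    fields[mi_col], species_prefix=species_prefix, aliases=aliases
                )
                gene = fields[gene_col].strip().upper()
                if not gene:
                    raise ValueError("empty gene symbol")
                score = float(fields[score_col]) if score_col is not None else None
            except (IndexError, ValueError, TargetError) as exc:
                if n_lines == 1:
                    continue  # header line
                n_bad += 1
                logger.warning("skipping malformed line %d of %s: %s", lineno, path, exc)
                continue
            pair = (mirna, gene)
            if pair in scores and score is not None and score <= scores[pair]:
                continue
            mapping.setdefault(mirna, set()).add(gene)
            if score is not None:
                scores[pair] = score
    if n_lines == 0:
        warnings.warn(f"prediction file {path} is empty")
    elif n_bad / n_lines > max_malformed_fraction:
        raise TargetError(
            f"{n_bad}/{n_lines} malformed lines in {path}; file likely in wrong dialect"
        )
    if n_bad:
        logger.info("%s: skipped %d of %d lines", path, n_bad, n_lines)
    return PredictionDB(source=source, mapping=mapping, scores=scores)


def read_gene_groups(paths: dict[str, str]) -> GeneGroupSet:
    """Read the five gene-group files (one symbol per line, '#' comments)."""
    groups = {}
    for name in GROUP_NAMES:
        if name not in paths:
            raise TargetError(f"missing gene-group file for {name}")
        symbols = set()
        with open(paths[name], encoding="utf-8") as fh:
            for line in fh:
                sym = line.split("#")[0].strip().upper()
                if sym:
                    symbols.add(sym)
        groups[name] = symbols
    return GeneGroupSet(groups=groups)


# ---------------------------------------------------------------------------
# filtering and intersection


def filter_beta_mirnas(sam_table: pd.DataFrame, min_fc: float = 3.0) -> list[str]:
    """Beta-direction miRNAs with fold change strictly above ``min_fc``."""
    if "direction" not in sam_table or "fold_change" not in sam_table:
        raise TargetError("SAM table lacks direction/fold_change columns")
    keep = (sam_table["direction"] == "beta") & (sam_table["fold_change"] > min_fc)
    return sam_table.loc[keep, "mirna"].tolist()


def intersect_targets(
    mirnas: list[str],
    dbs: list[PredictionDB],
    groups: GeneGroupSet,
    min_sources: int = 1,
    species_prefix: str = "hsa",
    aliases: dict[str, str] | None = None,
) -> TargetReport:
    """Cross-reference miRNA target predictions with the islet gene groups.

    For each (miRNA, database) pair the predicted genes are intersected
    with every group; the consensus column counts how many of the supplied
    databases predict that (miRNA, gene) pair at all.  Output rows are
    sorted by (mirna, group, source, gene), so the report is invariant to
    database row order and input miRNA order.  miRNAs found in no database
    are listed under ``unmatched`` rather than erroring.
    """
    canon = [normalize_mirna_id(m, species_prefix, aliases) for m in mirnas]
    canon = list(dict.fromkeys(canon))

    consensus: dict[tuple[str, str], int] = {}
    for mirna in canon:
        for db in dbs:
            for gene in db.targets_of(mirna):
                consensus[(mirna, gene)] = consensus.get((mirna, gene), 0) + 1

    rows = []
    unmatched = []
    for mirna in canon:
        hit_any = False
        for db in dbs:
            predicted = db.targets_of(mirna)
            if predicted:
                hit_any = True
            for gname in GROUP_NAMES:
                for gene in sorted(predicted & groups.groups[gname]):
                    if consensus[(mirna, gene)] >= min_sources:
                        rows.append(
                            (mirna, gname, db.source, gene, consensus[(mirna, gene)])
                        )
        if not hit_any:
            unmatched.append(mirna)

    rows_df = pd.DataFrame(
        rows, columns=["mirna", "group", "source", "gene", "consensus"]
    ).sort_values(["mirna", "group", "source", "gene"]).reset_index(drop=True)
    if rows_df.empty:
        summary = pd.DataFrame(columns=["mirna", "group", "source", "n_targets"])
    else:
        summary = (
            rows_df.groupby(["mirna", "group", "source"], as_index=False)
            .size()
            .rename(columns={"size": "n_targets"})
        )
    return TargetReport(rows=rows_df, summary=summary, unmatched=sorted(unmatched))
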