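"""Readers, writers, and packaged reference tables.

Dialects follow the conventions of the standard GWAS toolchain: summary
statistics are PLINK/METAL-style header-named TSV, motifs are JASPAR PFM or
MEME-minimal text, intervals are BED3 (0-based half-open), and the LD matrix
is a square TSV with SNP ids on both margins. SNP tables use 1-based
positions; the 0/1-based conversion happens only at the BED boundary.

Three reference tables from the source fine-mapping study are packaged
verbatim: the cohort roster ("table1"), the meta-analysis of the locus
("table2", 19 SNPs), and the epigenetic feature matrix of the significant
SNPs ("table3", 19 SNPs).

Writers emit a deterministic column order; p-values are formatted in
scientific notation with 3 significant digits (the style of the source
tables), so float columns round-trip to that precision and all other
columns round-trip exactly.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import (
    ASBObservation,
    AnnotationRecord,
    AssociationRecord,
    CohortInfo,
    LDMatrix,
    MetaResult,
    PWM,
    PriorityScore,
)

logger = logging.getLogger("regfine")

__all__ = [
    "RowError",
    "read_summary_stats",
    "write_summary_stats",
    "load_fixture",
    "fixture_cohorts",
    "fixture_annotations",
    "fixture_table2_records",
    "read_pfm",
    "read_bed_intervals",
    "read_asb_counts",
    "write_asb_counts",
    "write_meta_results",
    "read_meta_results",
    "write_priority_table",
    "read_priority_table",
    "write_annotations",
    "read_annotations",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_fasta",
    "load_yaml",
]

_FIXTURES = {"table1", "table2", "table3"}

#: Recognized header spellings, lower-cased. Extendable via the ``aliases``
#: argument of :func:`read_summary_stats`.
COLUMN_ALIASES = {
    "snp_id": ("snp", "snp_id", "rsid", "markername", "id"),
    "chrom": ("chr", "chrom", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "allele1": ("a1", "allele1", "ea", "effect_allele"),
    "allele2": ("a2", "allele2", "oa", "other_allele", "non_effect_allele"),
    "af1": ("af1", "eaf", "frq", "freq1", "maf"),
    "beta": ("beta", "b", "effect"),
    "se": ("se", "stderr", "standard_error"),
    "p": ("p", "pval", "p_value", "pvalue", "p-value"),
    "direction": ("direction", "dir", "sign"),
    "hwe_p": ("hwe_p", "hwe", "p_hwe"),
    "missingness": ("missingness", "f_miss", "fmiss"),
    "info": ("info", "imputation_quality", "rsq", "info_score"),
}

MANDATORY = ("snp_id", "allele1", "allele2", "p")


class RowError(NamedTuple):
    """A rejected input row: 1-based line number and the reason."""

    line: int
    reason: str


def _map_header(header: Sequence[str], aliases=None) -> dict:
    table = {k: tuple(v) for k, v in COLUMN_ALIASES.items()}
    if aliases:
        for field, names in aliases.items():
            table[field] = table.get(field, ()) + tuple(n.lower() for n in names)
    lower = [h.strip().lower() for h in header]
    mapping = {}
    for field, names in table.items():
        for name in names:
            if name in lower:
                mapping[field] = lower.index(name)
                break
    missing = [f for f in MANDATORY if f not in mapping]
    if missing:
        raise ValueError(
            f"summary-statistics file is missing mandatory column(s): "
            f"{', '.join(missing)} (header: {header})"
        )
    return mapping


def _parse_direction(token: str) -> int:
    token = token.strip()
    if token in ("+", "+1", "1"):
        return 1
    if token in ("-", "−", "-1"):
        return -1
    raise ValueError(f"unparseable direction {token!r}")


def read_summary_stats(
    path,
    cohort: Optional[CohortInfo] = None,
    aliases: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[list[AssociationRecord], list[RowError]]:
    """Read one cohort's summary statistics from a header-named TSV.

    Returns ``(records, rejected)``: one record per parseable data row, and
    a line-numbered report of rows rejected for domain violations (p outside
    (0, 1], unparseable numbers). Missing optional columns yield absent
    (None) fields. A missing mandatory column (SNP id, alleles, p) raises.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row")
        cols = _map_header(header, aliases)
        records: list[AssociationRecord] = []
        rejected: list[RowError] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                records.append(_parse_row(row, cols, cohort))
            except (ValueError, IndexError) as exc:
                rejected.append(RowError(lineno, str(exc)))
    if rejected:
        logger.warning("%s: rejected %d row(s); first: line %d: %s",
                       path, len(rejected), rejected[0].line, rejected[0].reason)
    return records, rejected


def _opt_float(row, cols, field) -> Optional[float]:
    if field not in cols:
        return None
    token = row[cols[field]].strip()
    if token in ("", "NA", "nan", "."):
        return None
    return float(token)


def _parse_row(row, cols, cohort) -> AssociationRecord:
    p = float(row[cols["p"]])
    beta = _opt_float(row, cols, "beta")
    if "direction" in cols:
        direction = _parse_direction(row[cols["direction"]])
    elif beta is not None:
        direction = 1 if beta >= 0 else -1
    else:
        direction = 1
    return AssociationRecord(
        snp_id=row[cols["snp_id"]].strip(),
        chrom=row[cols["chrom"]].strip() if "chrom" in cols else "",
        pos=int(row[cols["pos"]]) if "pos" in cols else 0,
        allele1=row[cols["allele1"]].strip().upper(),
        allele2=row[cols["allele2"]].strip().upper(),
        p=p,
        direction=direction,
        af1=_opt_float(row, cols, "af1"),
        beta=beta,
        se=_opt_float(row, cols, "se"),
        hwe_p=_opt_float(row, cols, "hwe_p"),
        missingness=_opt_float(row, cols, "missingness"),
        info=_opt_float(row, cols, "info"),
        cohort=cohort,
    )


def _fmt_p(p: Optional[float]) -> str:
    return "NA" if p is None else f"{p:.2E}"


def _fmt(x, nd=6) -> str:
    return "NA" if x is None else f"{x:.{nd}g}"


def write_summary_stats(records: Iterable[AssociationRecord], path) -> None:
    """Write records in the TSV dialect :func:`read_summary_stats` consumes."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["SNP", "CHR", "POS", "A1", "A2", "AF1", "BETA", "SE",
                    "P", "DIRECTION", "HWE_P", "F_MISS", "INFO"])
        for r in records:
            w.writerow([
                r.snp_id, r.chrom, r.pos, r.allele1, r.allele2,
                _fmt(r.af1), _fmt(r.beta), _fmt(r.se), _fmt_p(r.p),
                "+" if r.direction > 0 else "-",
                _fmt_p(r.hwe_p), _fmt(r.missingness), _fmt(r.info),
            ])


# ---------------------------------------------------------------------------
# Packaged reference tables


def load_fixture(name: str) -> pd.DataFrame:
    """Return a packaged reference table ("table1", "table2" or "table3")."""
    if name not in _FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {sorted(_FIXTURES)}"
        )
    ref = resources.files("regfine.data") / f"{name}.tsv"
    with resources.as_file(ref) as fp:
        df = pd.read_csv(fp, sep="\t", dtype={"regdb": str, "chrom": str})
    return df


def fixture_cohorts() -> list[CohortInfo]:
    """The four contributing cohorts of the packaged study (TOTAL excluded)."""
    df = load_fixture("table1")
    return [
        CohortInfo(name=row.population, n_cases=int(row.cases),
                   n_controls=int(row.controls), ancestry=str(row.cohort))
        for row in df.itertuples()
        if row.population != "TOTAL"
    ]


def fixture_annotations() -> list[AnnotationRecord]:
    """Table 3's raw feature columns as typed annotation records."""
    df = load_fixture("table3")
    out = []
    for row in df.itertuples():
        region = "intronic" if "intron" in row.function else (
            "intergenic" if "intergenic" in row.function else "other")
        out.append(AnnotationRecord(
            snp_id=row.snp, region_class=region, score_3d=float(row.score_3d),
            regdb_category=str(row.regdb), eqtl_count=int(row.eqtl),
            enhancer_count=int(row.enhancer), rsnp_flag=int(row.rsnp),
            pchic_flag=int(row.pchic), tfbs_flag=int(row.tfbs),
            asb_count=int(row.asb), chrom="15", pos=int(row.position),
        ))
    return out


def fixture_table2_records() -> dict[CohortInfo, list[AssociationRecord]]:
    """Per-cohort association records rebuilt from the packaged meta table.

    Each cohort's p-value column becomes one record per SNP; effect
    directions come from the (sign-consistent) printed direction strings.
    """
    cohorts = {c.name: c for c in fixture_cohorts()}
    col_for = {"Asian": "p_3as", "HC": "p_ch", "EU": "p_eu", "JAP": "p_jap"}
    df = load_fixture("table2")
    grouped: dict[CohortInfo, list[AssociationRecord]] = {}
    for name, col in col_for.items():
        cohort = cohorts[name]
        grouped[cohort] = [
            AssociationRecord(
                snp_id=row.snp, chrom="15", pos=int(row.position),
                allele1=row.a1, allele2=row.a2, p=float(getattr(row, col)),
                direction=1 if row.direction.startswith("+") else -1,
                cohort=cohort,
            )
            for row in df.itertuples()
        ]
    return grouped


# ---------------------------------------------------------------------------
# Motif files


def _normalize_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1) + 4.0 * pseudocount
    if np.any(totals <= 0):
        raise ValueError(
            "position with all-zero counts and zero pseudocount"
        )
    return (counts + pseudocount) / totals[:, None]


def read_pfm(path, pseudocount: float = 0.0,
             background: Optional[Sequence[float]] = None) -> list[PWM]:
    """Read motifs from a JASPAR PFM or MEME-minimal file.

    Counts (or probabilities) are renormalized per position with the given
    per-base pseudocount: (c + pc) / (sum + 4 pc). Background defaults to
    uniform 0.25 unless given here or stated in the MEME header.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("MEME") or "letter-probability matrix" in text:
        motifs = _parse_meme(text, pseudocount)
    else:
        motifs = _parse_jaspar(text, pseudocount)
    if background is not None:
        bg = np.asarray(background, dtype=float)
        for m in motifs:
            m.background = bg
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def _parse_matrix_rows(rows: list[list[float]], pseudocount: float,
                       motif_id: str, tf_name: str,
                       background=None) -> PWM:
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{motif_id}: ragged matrix rows {sorted(lengths)}")
    counts = np.array(rows, dtype=float)
    return PWM(
        motif_id=motif_id, tf_name=tf_name,
        probs=_normalize_counts(counts, pseudocount),
        background=(np.full(4, 0.25) if background is None
                    else np.asarray(background, dtype=float)),
    )


def _parse_jaspar(text: str, pseudocount: float) -> list[PWM]:
    motifs = []
    motif_id = tf_name = None
    base_rows: list[list[float]] = []

    def flush():
        if motif_id is None and not base_rows:
            return
        if len(base_rows) != 4:
            raise ValueError(
                f"{motif_id or '<unnamed>'}: expected 4 base rows, "
                f"got {len(base_rows)}"
            )
        lengths = {len(r) for r in base_rows}
        if len(lengths) != 1:
            raise ValueError(f"{motif_id}: ragged matrix rows")
        # JASPAR rows are per base (A, C, G, T) across positions
        counts = np.array(base_rows, dtype=float).T
        motifs.append(PWM(
            motif_id=motif_id or f"motif{len(motifs) + 1}",
            tf_name=tf_name or "",
            probs=_normalize_counts(counts, pseudocount),
        ))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if base_rows:
                flush()
                base_rows = []
            parts = line[1:].split(None, 1)
            motif_id = parts[0] if parts else ""
            tf_name = parts[1].strip() if len(parts) > 1 else ""
        else:
            body = line
            if body[:1].upper() in "ACGT" and not body[:1].isdigit():
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            base_rows.append([float(t) for t in body.split()])
    if base_rows or motif_id is not None:
        flush()
    return motifs


def _parse_meme(text: str, pseudocount: float) -> list[PWM]:
    motifs = []
    lines = iter(text.splitlines())
    background = None
    for line in lines:
        line = line.strip()
        if line.lower().startswith("background letter frequencies"):
            freq_line = next(lines, "").split()
            try:
                background = np.array(
                    [float(freq_line[i]) for i in (1, 3, 5, 7)]
                )
            except (IndexError, ValueError):
                background = None
        elif line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif{len(motifs)+1}"
            tf_name = parts[2] if len(parts) > 2 else ""
            rows: list[list[float]] = []
            for body in lines:
                body = body.strip()
                if not body:
                    if rows:
                        break
                    continue
                if body.lower().startswith("letter-probability"):
                    continue
                if body.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(t) for t in body.split()])
            if not rows:
                raise ValueError(f"{motif_id}: empty probability matrix")
            motifs.append(_parse_matrix_rows(
                rows, pseudocount, motif_id, tf_name, background))
    return motifs


# ---------------------------------------------------------------------------
# Intervals, read counts, result tables


def read_bed_intervals(path, strict: bool = False) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based, half-open).

    Rows with start >= end (zero-length or inverted) are rejected: skipped
    with a warning by default, or raised as ``ValueError`` when ``strict``.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError(f"start {start} >= end {end}")
            except (IndexError, ValueError) as exc:
                if strict:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("%s:%d: rejected BED row (%s)", path, lineno, exc)
                continue
            intervals.append((chrom, start, end))
    return intervals


def read_asb_counts(path) -> list[ASBObservation]:
    """Read allele-resolved read counts (TSV: SNP, CELL_LINE, REF, ALT)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return [
        ASBObservation(snp_id=str(row.snp), cell_line=str(row.cell_line),
                       ref_count=int(row.ref_count), alt_count=int(row.alt_count))
        for row in df.itertuples()
    ]


def write_asb_counts(observations: Iterable[ASBObservation], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["SNP", "CELL_LINE", "REF_COUNT", "ALT_COUNT"])
        for o in observations:
            w.writerow([o.snp_id, o.cell_line, o.ref_count, o.alt_count])


def write_meta_results(results: Iterable[MetaResult], path) -> None:
    """Write meta-analysis results as a METAL-like TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["SNP", "CHR", "POS", "A1", "A2", "Z", "P", "OR",
                    "CI_L", "CI_U", "Q", "HET_P", "DIRECTION", "N_COHORTS"])
        for r in results:
            w.writerow([
                r.snp_id, r.chrom, r.pos, r.allele1, r.allele2,
                _fmt(r.z_combined), _fmt_p(r.p_meta), _fmt(r.or_meta, 4),
                _fmt(r.ci_low, 4), _fmt(r.ci_high, 4), _fmt(r.q_stat, 4),
                _fmt(r.het_p, 4), r.direction_string, r.n_cohorts,
            ])


def read_meta_results(path) -> list[MetaResult]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "DIRECTION": str},
                     na_values=["NA"], keep_default_na=False)
    out = []
    for row in df.itertuples():
        def opt(x):
            return None if pd.isna(x) else float(x)
        out.append(MetaResult(
            snp_id=str(row.SNP), chrom=str(row.CHR), pos=int(row.POS),
            allele1=str(row.A1), allele2=str(row.A2),
            z_combined=float(row.Z), p_meta=float(row.P),
            or_meta=opt(row.OR), ci_low=opt(row.CI_L), ci_high=opt(row.CI_U),
            q_stat=float(row.Q), het_p=opt(row.HET_P),
            direction_string="" if pd.isna(row.DIRECTION) else str(row.DIRECTION),
            n_cohorts=int(row.N_COHORTS),
        ))
    return out


def write_priority_table(scores: Iterable[PriorityScore], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["SNP", "W3D", "WREGDB", "FEATURES", "TOTAL", "NOMINATED"])
        for s in scores:
            w.writerow([s.snp_id, s.w3d, s.wregdb, s.feature_sum,
                        s.total, int(s.nominated)])


def read_priority_table(path) -> list[PriorityScore]:
    df = pd.read_csv(path, sep="\t")
    return [
        PriorityScore(snp_id=str(r.SNP), w3d=int(r.W3D), wregdb=int(r.WREGDB),
                      feature_sum=int(r.FEATURES), total=int(r.TOTAL),
                      nominated=bool(r.NOMINATED))
        for r in df.itertuples()
    ]


def write_annotations(records: Iterable[AnnotationRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["SNP", "CHR", "POS", "REGION", "SCORE_3D", "REGDB",
                    "EQTL", "ENHANCER", "RSNP", "PCHIC", "TFBS", "ASB"])
        for r in records:
            w.writerow([r.snp_id, r.chrom, r.pos, r.region_class,
                        _fmt(r.score_3d), r.regdb_category, r.eqtl_count,
                        r.enhancer_count, r.rsnp_flag, r.pchic_flag,
                        r.tfbs_flag, r.asb_count])


def read_annotations(path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"REGDB": str, "CHR": str})
    return [
        AnnotationRecord(
            snp_id=str(r.SNP), region_class=str(r.REGION),
            score_3d=float(r.SCORE_3D), regdb_category=str(r.REGDB),
            eqtl_count=int(r.EQTL), enhancer_count=int(r.ENHANCER),
            rsnp_flag=int(r.RSNP), pchic_flag=int(r.PCHIC),
            tfbs_flag=int(r.TFBS), asb_count=int(r.ASB),
            chrom=str(r.CHR), pos=int(r.POS),
        )
        for r in df.itertuples()
    ]


def read_ld_matrix(path) -> LDMatrix:
    """Read a square r-squared TSV with SNP ids as both header and index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(snp_ids=[str(c) for c in df.columns],
                    r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_fasta(path) -> dict[str, str]:
    """Read a (small) FASTA file into {name: sequence}."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
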