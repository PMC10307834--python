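"""Readers, writers and validated in-memory tables for all external formats.

All genomic coordinates are 1-based and intervals are closed (inclusive at
both ends), matching both the array-manifest and VCF conventions.
Chromosome names are normalized by stripping any leading ``chr`` before any
join between tables.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, ParseError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Enums and core records
# ---------------------------------------------------------------------------

class Strand(str, enum.Enum):
    """Probe orientation relative to the reference genome."""

    F = "F"
    R = "R"


class DesignType(str, enum.Enum):
    """Infinium assay chemistry: paired-bead (I) or single-base extension (II)."""

    I = "I"
    II = "II"


def normalize_chromosome(chrom: str) -> str:
    """Return a bare chromosome name: ``chr6``/``Chr6``/``6`` all map to ``6``."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class RegionDefinition:
    """A named closed genomic interval, 1-based inclusive at both ends."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region {self.name!r}: start {self.start} > end {self.end}"
            )
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            normalize_chromosome(chromosome) == self.chromosome
            and self.start <= position <= self.end
        )

    @property
    def width(self) -> int:
        return self.end - self.start + 1


#: HLA region plus flanks analysed throughout (GRCh37/hg19).
HLA_FLANKING = RegionDefinition("hla_flanking", "6", 26_000_000, 35_000_000)
#: 5' end of HLA-F to 5' end of HLA-B (GRCh37/hg19).
HLA_CLASS_I = RegionDefinition("hla_class_i", "6", 29_691_241, 31_323_369)
#: 5' end of HLA-DRA to 3' end of HLA-DPB2 (GRCh37/hg19).
HLA_CLASS_II = RegionDefinition("hla_class_ii", "6", 32_407_619, 33_086_926)

REGIONS: Mapping[str, RegionDefinition] = {
    r.name: r for r in (HLA_FLANKING, HLA_CLASS_I, HLA_CLASS_II)
}


@dataclass(frozen=True)
class ProbeRecord:
    """One manifest entry.

    ``binding_pos`` is the cytosine of the target CpG for forward-strand
    probes and the adjacent guanine for reverse-strand probes, as annotated
    by the array manifest.
    """

    probe_id: str
    chromosome: str
    binding_pos: int
    strand: Strand
    design_type: DesignType
    gene: str | None = None
    feature: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        object.__setattr__(self, "strand", Strand(self.strand))
        object.__setattr__(self, "design_type", DesignType(self.design_type))
        if int(self.binding_pos) < 1:
            raise ValueError(f"binding_pos must be >= 1, got {self.binding_pos}")
        object.__setattr__(self, "binding_pos", int(self.binding_pos))


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide variant with a folded minor allele frequency."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if int(self.position) < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        object.__setattr__(self, "position", int(self.position))
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"not a SNV: {self.ref_allele}>{self.alt_allele} "
                f"at {self.chromosome}:{self.position}"
            )
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class SampleInfo:
    """One sample-sheet row."""

    sample_id: str
    group: str  # "case" | "control"
    dqb1_0602_carrier: bool
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

class BetaMatrix:
    """A probe x sample grid of fractions in [0, 1]; NaN marks missing.

    Used both for methylation beta values and for detection-P values (the
    two share shape and bounds).
    """

    def __init__(self, data: pd.DataFrame, bounds: tuple[float, float] | None = (0.0, 1.0)):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise DataError(f"duplicate probe_id {dup!r} in matrix")
        values = data.astype(float)
        if bounds is not None:
            lo, hi = bounds
            arr = values.to_numpy()
            bad = (arr < lo) | (arr > hi)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ParseError(
                    f"value {arr[i, j]} out of [{lo}, {hi}] at probe "
                    f"{values.index[i]!r}, sample {values.columns[j]!r}"
                )
        self._data = values
        self._data.index.name = "probe_id"

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def probe_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        keep = [p for p in self.probe_ids if p in set(probe_ids)]
        return BetaMatrix(self._data.loc[keep], bounds=None)

    def drop_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        drop = set(probe_ids)
        keep = [p for p in self.probe_ids if p not in drop]
        return BetaMatrix(self._data.loc[keep], bounds=None)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        return isinstance(other, BetaMatrix) and self._data.equals(other._data)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

#: canonical column name -> default file column name
DEFAULT_MANIFEST_COLUMNS: Mapping[str, str] = {
    "probe_id": "probe_id",
    "chromosome": "chromosome",
    "binding_pos": "binding_pos",
    "strand": "strand",
    "design_type": "design_type",
    "gene": "gene",
    "feature": "feature",
}

_REQUIRED_MANIFEST = ("probe_id", "chromosome", "binding_pos", "strand", "design_type")


def read_manifest(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[ProbeRecord]:
    """Read a tab-delimited array manifest into validated :class:`ProbeRecord` s.

    ``column_map`` maps canonical names (``probe_id``, ``chromosome``,
    ``binding_pos``, ``strand``, ``design_type``, optionally ``gene`` and
    ``feature``) onto the file's header names, so manifest dialects are a
    configuration concern, not a code change.
    """
    colmap = dict(DEFAULT_MANIFEST_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [colmap[c] for c in _REQUIRED_MANIFEST if colmap[c] not in df.columns]
    if missing:
        raise ConfigError(f"manifest {path}: missing required column(s) {missing}")

    records: list[ProbeRecord] = []
    errors: list[str] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header row
        row_d = dict(zip(df.columns, row))
        pid = row_d[colmap["probe_id"]]
        if pid in seen:
            raise ParseError(
                f"manifest {path}: duplicate probe_id {pid!r} "
                f"(rows {seen[pid]} and {i})"
            )
        seen[pid] = i
        try:
            pos = int(row_d[colmap["binding_pos"]].replace(",", ""))
        except ValueError:
            errors.append(
                f"row {i}: unparseable coordinate "
                f"{row_d[colmap['binding_pos']]!r}"
            )
            continue
        gene = row_d.get(colmap["gene"], "") or None
        feature = row_d.get(colmap["feature"], "") or None
        try:
            records.append(
                ProbeRecord(
                    probe_id=pid,
                    chromosome=row_d[colmap["chromosome"]],
                    binding_pos=pos,
                    strand=row_d[colmap["strand"]],
                    design_type=row_d[colmap["design_type"]],
                    gene=gene,
                    feature=feature,
                )
            )
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ParseError(f"manifest {path}: " + "; ".join(errors))
    return records


def fold_maf(frequency: float) -> float:
    """Fold an allele frequency onto the minor-allele scale: f > 0.5 -> 1 - f."""
    f = float(frequency)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {f}")
    return 1.0 - f if f > 0.5 else f


@dataclass
class AfPanelStats:
    """Bookkeeping from reading an allele-frequency panel."""

    n_records: int = 0
    n_snvs: int = 0
    n_indels_skipped: int = 0
    n_missing_af: int = 0
    n_folded: int = 0


def read_af_panel(
    path: str | Path, af_field: str = "AF"
) -> tuple[list[SnpRecord], AfPanelStats]:
    """Read a VCF allele-frequency panel into :class:`SnpRecord` s.

    Multi-allelic records are expanded to one record per ALT allele;
    frequencies above 0.5 are folded to MAF; indels are skipped and counted;
    records lacking the AF field are skipped with a counted warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"AF panel not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on malformed input
        raise ParseError(f"malformed VCF {path}: {exc}") from exc

    stats = AfPanelStats()
    records: list[SnpRecord] = []
    for variant in vcf:
        stats.n_records += 1
        alts = variant.ALT or []
        raw_af = variant.INFO.get(af_field)
        if raw_af is None:
            stats.n_missing_af += 1
            continue
        afs = list(raw_af) if isinstance(raw_af, (tuple, list, np.ndarray)) else [raw_af]
        if len(afs) != len(alts):
            stats.n_missing_af += 1
            continue
        for alt, f in zip(alts, afs):
            if len(variant.REF) != 1 or len(alt) != 1:
                stats.n_indels_skipped += 1
                continue
            f = float(f)
            maf = fold_maf(f)
            if maf != f:
                stats.n_folded += 1
            records.append(
                SnpRecord(
                    chromosome=variant.CHROM,
                    position=variant.POS,
                    ref_allele=variant.REF,
                    alt_allele=alt,
                    maf=maf,
                )
            )
            stats.n_snvs += 1
    if stats.n_missing_af:
        log.warning(
            "%s: %d record(s) lacked INFO/%s and were skipped",
            path, stats.n_missing_af, af_field,
        )
    if stats.n_indels_skipped:
        log.info("%s: skipped %d indel allele(s)", path, stats.n_indels_skipped)
    return records, stats


def read_matrix(
    path: str | Path, bounds: tuple[float, float] | None = (0.0, 1.0)
) -> BetaMatrix:
    """Read a probe x sample TSV (first column probe_id) into a BetaMatrix.

    Empty cells are preserved as missing (NaN), never coerced to zero.
    The same reader serves beta-value and detection-P matrices; both are
    bounded to [0, 1] by default.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    empty = raw.apply(lambda col: col.str.strip() == "")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~empty
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"matrix {path}: non-numeric value {raw.iat[i, j]!r} at probe "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    try:
        return BetaMatrix(numeric, bounds=bounds)
    except ParseError as exc:
        raise ParseError(f"matrix {path}: {exc}") from exc


_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _parse_bool(value: str, context: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ParseError(f"{context}: cannot parse boolean {value!r}")


def read_samples(path: str | Path) -> list[SampleInfo]:
    """Read the sample sheet (sample_id, group, dqb1_0602_carrier, age, sex, bmi)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("sample_id", "group", "dqb1_0602_carrier")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"sample sheet {path}: missing column(s) {missing}")
    out: list[SampleInfo] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ParseError(f"sample sheet {path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            out.append(
                SampleInfo(
                    sample_id=sid,
                    group=row["group"],
                    dqb1_0602_carrier=_parse_bool(
                        row["dqb1_0602_carrier"], f"sample {sid}"
                    ),
                    age=float(row["age"]) if row.get("age", "") != "" else None,
                    sex=row.get("sex") or None,
                    bmi=float(row["bmi"]) if row.get("bmi", "") != "" else None,
                )
            )
        except ValueError as exc:
            raise ParseError(f"sample sheet {path}, row {i + 2}: {exc}") from exc
    return out


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read per-sample per-allele RNA read counts.

    Returns a validated DataFrame with columns
    ``sample_id, gene, allele, read_count, allele_length``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str, "allele": str})
    required = ("sample_id", "gene", "allele", "read_count", "allele_length")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"allele counts {path}: missing column(s) {missing}")
    if (df["read_count"] < 0).any():
        bad = df.loc[df["read_count"] < 0].iloc[0]
        raise ParseError(
            f"allele counts {path}: negative read_count for "
            f"({bad['sample_id']}, {bad['allele']})"
        )
    if (df["allele_length"] <= 0).any():
        bad = df.loc[df["allele_length"] <= 0].iloc[0]
        raise ParseError(
            f"allele counts {path}: non-positive allele_length for {bad['allele']}"
        )
    dup = df.duplicated(subset=["sample_id", "gene", "allele"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ParseError(
            f"allele counts {path}: duplicate entry for "
            f"({bad['sample_id']}, {bad['gene']}, {bad['allele']})"
        )
    return df[list(required)]


def read_blocklist(path: str | Path) -> set[str]:
    """Read a blocklist file: one probe_id per line, '#' comments allowed."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


def load_config(path: str | Path) -> dict:
    """Load a YAML config file (column maps, thresholds, region definitions)."""
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path}: top level must be a mapping")
    return cfg


def parse_region(text: str) -> RegionDefinition:
    """Parse a region name (``hla_flanking``) or ``chrom:start-end`` literal."""
    if text in REGIONS:
        return REGIONS[text]
    try:
        chrom, span = text.split(":")
        start_s, end_s = span.replace(",", "").split("-")
        return RegionDefinition(text, chrom, int(start_s), int(end_s))
    except ValueError as exc:
        raise ConfigError(
            f"cannot parse region {text!r}; expected a known name "
            f"({', '.join(REGIONS)}) or chrom:start-end"
        ) from exc


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_manifest(probes: Sequence[ProbeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "chromosome": [p.chromosome for p in probes],
            "binding_pos": [p.binding_pos for p in probes],
            "strand": [p.strand.value for p in probes],
            "design_type": [p.design_type.value for p in probes],
            "gene": [p.gene or "" for p in probes],
            "feature": [p.feature or "" for p in probes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id")


def write_samples(samples: Sequence[SampleInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "dqb1_0602_carrier": [int(s.dqb1_0602_carrier) for s in samples],
            "age": [s.age for s in samples],
            "sex": [s.sex for s in samples],
            "bmi": [s.bmi for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _sorted_for_output(df: pd.DataFrame, p_column: str) -> pd.DataFrame:
    """Deterministic row order: ascending P (missing last), ties by probe_id."""
    return df.sort_values(
        by=[p_column, "probe_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def write_dmp_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write DMP association results sorted by P then probe_id."""
    if results.empty:
        raise DataError("refusing to write an empty DMP table")
    df = results.reset_index() if results.index.name == "probe_id" else results.copy()
    out = _sorted_for_output(df, "p_ttest")
    out.to_csv(path, sep="\t", index=False)


def write_audit_table(audit_df: pd.DataFrame, path: str | Path) -> None:
    """Write the per-probe audit table sorted by probe_id."""
    if audit_df.empty:
        raise DataError("refusing to write an empty audit table")
    out = audit_df.sort_values("probe_id", kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def write_expression_table(results: pd.DataFrame, path: str | Path) -> None:
    if results.empty:
        raise DataError("refusing to write an empty expression table")
    results.to_csv(path, sep="\t", index=False)


def write_blocklist(probe_ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(set(probe_ids)):
            fh.write(pid + "\n")


def write_af_panel(snps: Sequence[SnpRecord], path: str | Path) -> None:
    """Write SNP records as a minimal VCF 4.2 file (AF holds the folded MAF)."""
    ordered = sorted(snps, key=lambda s: (s.chromosome, s.position, s.alt_allele))
    contigs = sorted({s.chromosome for s in ordered})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
        )
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in ordered:
            fh.write(
                f"{s.chromosome}\t{s.position}\t.\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\t.\tAF={s.maf:.6g}\n"
            )
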