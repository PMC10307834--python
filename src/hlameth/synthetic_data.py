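"""Synthetic inputs with the statistical structure of the study cohort.

Generates every pipeline input — manifest, allele-frequency panel (VCF),
beta and detection-P matrices, sample sheet, per-allele RNA counts — plus a
machine-readable ground-truth ledger, all deterministically from one seed.

Default cohort structure: 42 cases (all DQB1*06:02 carriers) vs 42 controls
(8 carriers).  Planted methylation effects are either ``direct`` (case mean
shifted) or ``carrier_mediated`` (carrier mean shifted regardless of case
status); beta noise is Beta-distributed with a concentration chosen so
per-probe SD is roughly 0.02-0.04, the scale at which 0.02-0.05 group
shifts are detectable at n = 42 per group.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    HLA_FLANKING,
    BetaMatrix,
    ProbeRecord,
    RegionDefinition,
    SampleInfo,
    SnpRecord,
    write_af_panel,
    write_manifest,
    write_matrix,
    write_samples,
)
from .probe_reliability import classify_snp

MECHANISMS = ("direct", "carrier_mediated", "null")


@dataclass(frozen=True)
class EffectProbe:
    """A planted methylation effect on one probe."""

    probe_id: str
    delta: float
    mechanism: str  # direct | carrier_mediated | null

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not -1.0 < self.delta < 1.0:
            raise ValueError(f"delta must keep means in (0,1), got {self.delta}")


@dataclass(frozen=True)
class PlannedSnp:
    """A SNP planted at an exact offset from a named probe."""

    probe_id: str
    offset: int
    maf: float

    def __post_init__(self) -> None:
        if not -15 <= self.offset <= 15:
            raise ValueError(f"offset must be in [-15, 15], got {self.offset}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class AlleleSpec:
    """One allele in the expression model.

    ``rate`` is the relative per-copy expression rate; ``frequency`` is the
    draw probability when assigning genotypes (None for the reference,
    which is assigned through carrier status).
    """

    name: str
    gene: str
    length: int
    rate: float
    frequency: float | None = None


def _default_dqb1_alleles() -> list[AlleleSpec]:
    return [
        AlleleSpec("DQB1*06:02", "DQB1", 786, 1.00, None),
        AlleleSpec("DQB1*05:01", "DQB1", 790, 0.55, 0.24),
        AlleleSpec("DQB1*06:01", "DQB1", 788, 0.50, 0.18),
        AlleleSpec("DQB1*05:03", "DQB1", 784, 0.60, 0.10),
        AlleleSpec("DQB1*06:09", "DQB1", 788, 0.70, 0.04),
        AlleleSpec("DQB1*03:01", "DQB1", 786, 0.30, 0.20),
        AlleleSpec("DQB1*03:02", "DQB1", 785, 0.25, 0.14),
        AlleleSpec("DQB1*04:01", "DQB1", 782, 0.20, 0.10),
    ]


def _default_background_alleles() -> list[AlleleSpec]:
    # Other HLA genes stabilize the per-million denominator.
    return [
        AlleleSpec("DRB1*15:01", "DRB1", 801, 0.90, 0.40),
        AlleleSpec("DRB1*04:05", "DRB1", 801, 0.80, 0.30),
        AlleleSpec("DRB1*01:01", "DRB1", 801, 0.85, 0.30),
        AlleleSpec("DPB1*05:01", "DPB1", 777, 0.50, 0.45),
        AlleleSpec("DPB1*04:02", "DPB1", 777, 0.45, 0.30),
        AlleleSpec("DPB1*02:01", "DPB1", 777, 0.55, 0.25),
    ]


@dataclass
class AlleleModel:
    """Per-allele expression rates plus the case-specific multiplier."""

    dqb1_alleles: list[AlleleSpec] = field(default_factory=_default_dqb1_alleles)
    background_alleles: list[AlleleSpec] = field(
        default_factory=_default_background_alleles
    )
    reference_allele: str = "DQB1*06:02"
    case_multiplier: float = 1.0
    multiplier_scope: str = "non_reference"  # non_reference | dqb1_05_06
    sequencing_depth: float = 0.5  # mean count = rate * length * depth * dosage
    nb_dispersion: float = 50.0

    def __post_init__(self) -> None:
        if self.multiplier_scope not in ("non_reference", "dqb1_05_06"):
            raise ValueError(f"bad multiplier_scope {self.multiplier_scope!r}")
        if self.case_multiplier <= 0:
            raise ValueError("case_multiplier must be > 0")


@dataclass
class SimulationSpec:
    """Everything needed to generate one synthetic dataset."""

    n_cases: int = 42
    n_controls: int = 42
    carrier_count_cases: int = 42
    carrier_count_controls: int = 8
    n_probes: int = 400
    region: RegionDefinition = HLA_FLANKING
    effect_probes: list[EffectProbe] = field(default_factory=list)
    beta_concentration: float = 250.0
    snp_plan: list[PlannedSnp] = field(default_factory=list)
    n_background_snps: int = 300
    detp_fail_rate: float = 0.01
    allele_model: AlleleModel = field(default_factory=AlleleModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ConfigError(f"n_probes must be >= 1, got {self.n_probes}")
        if self.carrier_count_cases > self.n_cases:
            raise ConfigError(
                f"carrier_count_cases {self.carrier_count_cases} exceeds "
                f"n_cases {self.n_cases}"
            )
        if self.carrier_count_controls > self.n_controls:
            raise ConfigError(
                f"carrier_count_controls {self.carrier_count_controls} exceeds "
                f"n_controls {self.n_controls}"
            )
        if self.beta_concentration <= 2:
            raise ConfigError("beta_concentration must exceed 2")

    def probe_id(self, i: int) -> str:
        """Deterministic probe id for index ``i`` (0-based)."""
        return f"cg{i + 1:08d}"


@dataclass
class GroundTruth:
    """What the generator planted, keyed so recovery can be scored exactly."""

    probes: dict = field(default_factory=dict)
    snps: list = field(default_factory=list)
    alleles: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "probes": self.probes,
            "snps": self.snps,
            "alleles": self.alleles,
            "cohort": self.cohort,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _stage_rngs(seed: int, n: int = 5) -> list[np.random.Generator]:
    """Derive independent per-stage generators from the single top seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _unique_positions(
    rng: np.random.Generator, region: RegionDefinition, n: int
) -> np.ndarray:
    """n distinct 1-based positions inside the region, sorted."""
    if n > region.width:
        raise ConfigError(f"cannot place {n} distinct positions in {region.name}")
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(region.start, region.end + 1, size=n - len(chosen) + 16)
        chosen.update(int(x) for x in draw)
    return np.array(sorted(chosen)[:n], dtype=np.int64)


_GENES = ("HLA-DRA", "HLA-DRB1", "HLA-DQB1", "GABBR1", "COL11A2", "TNXB", "")
_FEATURES = ("Body", "TSS200", "TSS1500", "5'UTR", "")


def gen_manifest(spec: SimulationSpec, rng: np.random.Generator) -> list[ProbeRecord]:
    """Probes uniformly placed in the region with random strand/design."""
    positions = _unique_positions(rng, spec.region, spec.n_probes)
    strands = rng.choice(["F", "R"], size=spec.n_probes)
    designs = rng.choice(["I", "II"], size=spec.n_probes)
    genes = rng.choice(_GENES, size=spec.n_probes)
    features = rng.choice(_FEATURES, size=spec.n_probes)
    return [
        ProbeRecord(
            probe_id=spec.probe_id(i),
            chromosome=spec.region.chromosome,
            binding_pos=int(positions[i]),
            strand=str(strands[i]),
            design_type=str(designs[i]),
            gene=str(genes[i]) or None,
            feature=str(features[i]) or None,
        )
        for i in range(spec.n_probes)
    ]


_BASES = np.array(list("ACGT"))


def gen_af_panel(
    spec: SimulationSpec,
    manifest: Sequence[ProbeRecord],
    rng: np.random.Generator,
) -> tuple[list[SnpRecord], list[dict]]:
    """Planted SNPs at exact probe offsets plus log-uniform background MAFs.

    The truth entry for each planted SNP records the influence category the
    window table assigns it (None when the offset is uninfluential).
    """
    by_id = {p.probe_id: p for p in manifest}
    snps: list[SnpRecord] = []
    truth: list[dict] = []
    used: set[tuple[int, str]] = set()

    for plan in spec.snp_plan:
        probe = by_id.get(plan.probe_id)
        if probe is None:
            raise ConfigError(f"snp_plan names unknown probe {plan.probe_id!r}")
        pos = probe.binding_pos + plan.offset
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        snp = SnpRecord(spec.region.chromosome, pos, str(ref), str(alt), plan.maf)
        cat = classify_snp(probe, snp)
        snps.append(snp)
        used.add((pos, str(alt)))
        truth.append(
            {
                "chromosome": snp.chromosome,
                "position": pos,
                "ref": str(ref),
                "alt": str(alt),
                "maf": plan.maf,
                "planted_for": plan.probe_id,
                "offset": plan.offset,
                "expected_category": cat.value if cat else None,
            }
        )

    # background: MAF spectrum spanning 0.001-0.5 (log-uniform mixture)
    n_bg = spec.n_background_snps
    positions = rng.integers(spec.region.start, spec.region.end + 1, size=n_bg)
    mafs = 10 ** rng.uniform(np.log10(0.001), np.log10(0.5), size=n_bg)
    for pos, maf in zip(positions, mafs):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        key = (int(pos), str(alt))
        if key in used:
            continue
        used.add(key)
        snp = SnpRecord(spec.region.chromosome, int(pos), str(ref), str(alt), float(maf))
        snps.append(snp)
        truth.append(
            {
                "chromosome": snp.chromosome,
                "position": int(pos),
                "ref": str(ref),
                "alt": str(alt),
                "maf": float(maf),
                "planted_for": None,
                "offset": None,
                "expected_category": None,
            }
        )
    return snps, truth


def gen_cohort(spec: SimulationSpec, rng: np.random.Generator) -> list[SampleInfo]:
    """Exactly the configured carrier counts per group; seeded demographics."""
    samples: list[SampleInfo] = []
    n_total = spec.n_cases + spec.n_controls
    ages = np.clip(rng.normal(35, 10, size=n_total), 18, 70).round(1)
    bmis = np.clip(rng.normal(22, 3, size=n_total), 15, 40).round(1)
    sexes = rng.choice(["F", "M"], size=n_total)
    case_carriers = set(rng.choice(spec.n_cases, spec.carrier_count_cases, replace=False))
    ctrl_carriers = set(
        rng.choice(spec.n_controls, spec.carrier_count_controls, replace=False)
    )
    for i in range(spec.n_cases):
        samples.append(
            SampleInfo(
                sample_id=f"case{i + 1:03d}",
                group="case",
                dqb1_0602_carrier=i in case_carriers,
                age=float(ages[i]),
                sex=str(sexes[i]),
                bmi=float(bmis[i]),
            )
        )
    for i in range(spec.n_controls):
        samples.append(
            SampleInfo(
                sample_id=f"ctrl{i + 1:03d}",
                group="control",
                dqb1_0602_carrier=i in ctrl_carriers,
                age=float(ages[spec.n_cases + i]),
                sex=str(sexes[spec.n_cases + i]),
                bmi=float(bmis[spec.n_cases + i]),
            )
        )
    return samples


def _effect_mu_interval(delta: float) -> tuple[float, float]:
    """Baseline-mean interval keeping both group means inside (0.02, 0.98)."""
    lo = max(0.02, 0.02 - delta)
    hi = min(0.98, 0.98 - delta)
    return lo, hi


def gen_beta(
    spec: SimulationSpec,
    cohort: Sequence[SampleInfo],
    manifest: Sequence[ProbeRecord],
    rng: np.random.Generator,
) -> tuple[BetaMatrix, BetaMatrix, dict]:
    """Beta and detection-P matrices plus per-probe truth.

    Null probes share one Beta(mu*k, (1-mu)*k) across groups; ``direct``
    probes shift the case mean by delta; ``carrier_mediated`` probes shift
    the carrier mean by delta regardless of case status.  Detection-P
    failures (values >= 0.01) are injected independently per cell.
    """
    effects = {e.probe_id: e for e in spec.effect_probes}
    unknown = set(effects) - {p.probe_id for p in manifest}
    if unknown:
        raise ConfigError(f"effect_probes name unknown probe(s): {sorted(unknown)[:3]}")

    sample_ids = [s.sample_id for s in cohort]
    is_case = np.array([s.group == "case" for s in cohort], dtype=float)
    is_carrier = np.array([s.dqb1_0602_carrier for s in cohort], dtype=float)
    n_probes, n_samples = len(manifest), len(cohort)

    mus = rng.uniform(0.1, 0.9, size=n_probes)
    truth_probes: dict = {}
    mean_grid = np.empty((n_probes, n_samples))
    for i, probe in enumerate(manifest):
        eff = effects.get(probe.probe_id)
        if eff is None or eff.mechanism == "null":
            mu, delta, mech = mus[i], 0.0, "null"
            shift = np.zeros(n_samples)
        else:
            lo, hi = _effect_mu_interval(eff.delta)
            mu = float(np.clip(mus[i], lo, hi))
            delta, mech = eff.delta, eff.mechanism
            shift = delta * (is_case if mech == "direct" else is_carrier)
        mean_grid[i] = mu + shift
        truth_probes[probe.probe_id] = {"mechanism": mech, "delta": delta, "mu": mu}

    k = spec.beta_concentration
    values = rng.beta(mean_grid * k, (1.0 - mean_grid) * k)
    betas = BetaMatrix(
        pd.DataFrame(values, index=[p.probe_id for p in manifest], columns=sample_ids),
        bounds=None,
    )

    fail = rng.random((n_probes, n_samples)) < spec.detp_fail_rate
    detp_vals = np.where(
        fail,
        rng.uniform(0.01, 1.0, size=fail.shape),
        rng.uniform(0.0, 0.009, size=fail.shape),
    )
    detp = BetaMatrix(
        pd.DataFrame(detp_vals, index=[p.probe_id for p in manifest], columns=sample_ids),
        bounds=None,
    )
    return betas, detp, truth_probes


def _in_multiplier_scope(model: AlleleModel, allele: str) -> bool:
    from .allele_expression import SUBLINEAGE_05_06, sublineage_of

    if allele == model.reference_allele:
        return False
    if model.multiplier_scope == "non_reference":
        return allele_gene_matches_reference(model, allele)
    return sublineage_of(allele) == SUBLINEAGE_05_06


def allele_gene_matches_reference(model: AlleleModel, allele: str) -> bool:
    from .allele_expression import allele_gene

    return allele_gene(allele) == allele_gene(model.reference_allele)


def gen_allele_counts(
    spec: SimulationSpec,
    cohort: Sequence[SampleInfo],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Per-sample per-allele negative-binomial read counts plus allele truth.

    Carriers get one reference allele plus one draw from the non-reference
    DQB1 pool; non-carriers get two non-reference draws.  Homozygous draws
    collapse to one row with dosage 2.  The case multiplier scales the
    count mean of in-scope alleles in case samples only.
    """
    model = spec.allele_model
    pool = [a for a in model.dqb1_alleles if a.name != model.reference_allele]
    ref = next(
        (a for a in model.dqb1_alleles if a.name == model.reference_allele), None
    )
    if ref is None:
        raise ConfigError(f"allele model lacks reference {model.reference_allele!r}")
    freqs = np.array([a.frequency for a in pool], dtype=float)
    if np.any(np.isnan(freqs)) or freqs.sum() <= 0:
        raise ConfigError("non-reference DQB1 alleles need draw frequencies")
    freqs = freqs / freqs.sum()

    bg = model.background_alleles
    bg_by_gene: dict[str, list[AlleleSpec]] = {}
    for a in bg:
        bg_by_gene.setdefault(a.gene, []).append(a)

    r = model.nb_dispersion
    rows: list[dict] = []
    for s in cohort:
        genotype: dict[str, tuple[AlleleSpec, int]] = {}

        def _add(a: AlleleSpec) -> None:
            prev = genotype.get(a.name)
            genotype[a.name] = (a, (prev[1] + 1) if prev else 1)

        if s.dqb1_0602_carrier:
            _add(ref)
            _add(pool[rng.choice(len(pool), p=freqs)])
        else:
            for _ in range(2):
                _add(pool[rng.choice(len(pool), p=freqs)])
        for gene_alleles in bg_by_gene.values():
            gf = np.array([a.frequency for a in gene_alleles], dtype=float)
            gf = gf / gf.sum()
            for _ in range(2):
                _add(gene_alleles[rng.choice(len(gene_alleles), p=gf)])

        for name in sorted(genotype):
            a, dosage = genotype[name]
            mean = a.rate * a.length * model.sequencing_depth * dosage
            if s.group == "case" and _in_multiplier_scope(model, name):
                mean *= model.case_multiplier
            count = int(rng.negative_binomial(r, r / (r + mean))) if mean > 0 else 0
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "gene": a.gene,
                    "allele": name,
                    "read_count": count,
                    "allele_length": a.length,
                }
            )

    truth_alleles = {
        a.name: {
            "gene": a.gene,
            "length": a.length,
            "rate": a.rate,
            "in_multiplier_scope": _in_multiplier_scope(model, a.name),
        }
        for a in (model.dqb1_alleles + bg)
    }
    return pd.DataFrame(rows), truth_alleles


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """A ready-to-run spec with planted SNPs and effects of every mechanism."""
    spec = SimulationSpec(seed=seed, **overrides)
    if not spec.snp_plan:
        plan = []
        offsets = [-9, -4, -1, 0, 1, 2, 3, 5, 6, 7, 10, 11, -10, -5]
        mafs = [0.3, 0.12, 0.06, 0.04, 0.02, 0.015, 0.008, 0.25]
        for j in range(min(30, spec.n_probes)):
            plan.append(
                PlannedSnp(
                    probe_id=spec.probe_id(j),
                    offset=offsets[j % len(offsets)],
                    maf=mafs[j % len(mafs)],
                )
            )
        spec.snp_plan = plan
    if not spec.effect_probes:
        effects = []
        base = min(40, spec.n_probes) - 1
        for j, delta in zip(range(5), (-0.05, -0.04, -0.03, 0.04, -0.02)):
            effects.append(EffectProbe(spec.probe_id(base - j), delta, "direct"))
        for j, delta in zip(range(5, 8), (-0.18, -0.19, 0.15)):
            effects.append(EffectProbe(spec.probe_id(base - j), delta, "carrier_mediated"))
        spec.effect_probes = effects
    return spec


def simulate_all(spec: SimulationSpec, outdir: str | Path) -> tuple[dict, GroundTruth]:
    """Generate everything, write all artifacts, return paths + ground truth.

    Byte-identical outputs for identical specs: all randomness flows from
    ``spec.seed`` through per-stage spawned generators, and no output embeds
    timestamps.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_manifest, rng_panel, rng_cohort, rng_beta, rng_alleles = _stage_rngs(spec.seed)

    manifest = gen_manifest(spec, rng_manifest)
    snps, truth_snps = gen_af_panel(spec, manifest, rng_panel)
    cohort = gen_cohort(spec, rng_cohort)
    betas, detp, truth_probes = gen_beta(spec, cohort, manifest, rng_beta)
    counts, truth_alleles = gen_allele_counts(spec, cohort, rng_alleles)

    truth = GroundTruth(
        probes=truth_probes,
        snps=truth_snps,
        alleles=truth_alleles,
        cohort={
            "n_cases": spec.n_cases,
            "n_controls": spec.n_controls,
            "carrier_count_cases": spec.carrier_count_cases,
            "carrier_count_controls": spec.carrier_count_controls,
            "seed": spec.seed,
        },
    )

    paths = {
        "manifest": outdir / "manifest.tsv",
        "panel": outdir / "panel.vcf",
        "beta": outdir / "beta.tsv",
        "detp": outdir / "detp.tsv",
        "samples": outdir / "samples.tsv",
        "allele_counts": outdir / "allele_counts.tsv",
        "truth": outdir / "truth.json",
    }
    write_manifest(manifest, paths["manifest"])
    write_af_panel(snps, paths["panel"])
    write_matrix(betas, paths["beta"])
    write_matrix(detp, paths["detp"])
    write_samples(cohort, paths["samples"])
    counts.to_csv(paths["allele_counts"], sep="\t", index=False)
    truth.write(paths["truth"])
    return {k: str(v) for k, v in paths.items()}, truth
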