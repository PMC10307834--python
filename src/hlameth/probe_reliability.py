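"""SNP-influence classification of methylation-array probes.

A SNP falling inside the probe-binding sequence near the 3' end lowers the
probe's affinity and makes the measured methylation rate untrustworthy.
Each of the four (strand x design-type) probe layouts has a fixed window of
influential offsets around the annotated binding position, split into three
severity categories:

``ONSITE``
    the interrogated CpG site itself (plus the flanking extension base for
    Type I probes) — strongest effect;
``5nt``
    1-5 nt from the 3' end — moderate effect;
``10nt``
    6-10 nt from the 3' end — small effect.

Offsets are ``snp.position - probe.binding_pos`` in genomic coordinates.
"""
from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import DataError
from .io_formats import DesignType, ProbeRecord, SnpRecord, Strand


class InfluenceCategory(str, enum.Enum):
    ONSITE = "ONSITE"
    NT5 = "5nt"
    NT10 = "10nt"


#: Higher value = stronger expected effect on probe affinity.
SEVERITY: Mapping[InfluenceCategory, int] = {
    InfluenceCategory.ONSITE: 3,
    InfluenceCategory.NT5: 2,
    InfluenceCategory.NT10: 1,
}


@dataclass(frozen=True)
class InfluenceWindow:
    """The influential offset sets for one (strand, design-type) layout."""

    strand: Strand
    design_type: DesignType
    onsite_offsets: frozenset[int]
    nt5_offsets: frozenset[int]
    nt10_offsets: frozenset[int]

    def __post_init__(self) -> None:
        sets = (self.onsite_offsets, self.nt5_offsets, self.nt10_offsets)
        total = len(self.onsite_offsets | self.nt5_offsets | self.nt10_offsets)
        if total != sum(len(s) for s in sets):
            raise ValueError("influence windows must be pairwise disjoint")
        expected = 12 if self.design_type == DesignType.I else 11
        if total != expected:
            raise ValueError(
                f"window for ({self.strand.value}, {self.design_type.value}) "
                f"covers {total} offsets, expected {expected}"
            )

    @property
    def all_offsets(self) -> frozenset[int]:
        return self.onsite_offsets | self.nt5_offsets | self.nt10_offsets

    def category_of(self, offset: int) -> InfluenceCategory | None:
        if offset in self.onsite_offsets:
            return InfluenceCategory.ONSITE
        if offset in self.nt5_offsets:
            return InfluenceCategory.NT5
        if offset in self.nt10_offsets:
            return InfluenceCategory.NT10
        return None


def _window(strand: Strand, design: DesignType, onsite, nt5, nt10) -> InfluenceWindow:
    return InfluenceWindow(
        strand, design, frozenset(onsite), frozenset(nt5), frozenset(nt10)
    )


# Hard-coded offset tables for the four layouts.  Forward-strand probes read
# downstream of the binding position; reverse-strand probes read upstream,
# and their annotated position is the guanine of the CpG, which shifts every
# window by one.
_WINDOWS: Mapping[tuple[Strand, DesignType], InfluenceWindow] = {
    (Strand.F, DesignType.I): _window(
        Strand.F, DesignType.I, (-1, 0), range(1, 6), range(6, 11)
    ),
    (Strand.F, DesignType.II): _window(
        Strand.F, DesignType.II, (0,), range(1, 6), range(6, 11)
    ),
    (Strand.R, DesignType.I): _window(
        Strand.R, DesignType.I, (1, 2), range(-4, 1), range(-9, -4)
    ),
    (Strand.R, DesignType.II): _window(
        Strand.R, DesignType.II, (1,), range(-4, 1), range(-9, -4)
    ),
}


def influence_window(strand: Strand | str, design_type: DesignType | str) -> InfluenceWindow:
    """Return the influential-offset table for one of the four probe layouts."""
    return _WINDOWS[(Strand(strand), DesignType(design_type))]


def classify_snp(probe: ProbeRecord, snp: SnpRecord) -> InfluenceCategory | None:
    """Classify one SNP's influence on one probe, or None if uninfluential.

    The probe and SNP must be on the same (normalized) chromosome.
    """
    if probe.chromosome != snp.chromosome:
        raise DataError(
            f"chromosome mismatch: probe {probe.probe_id} on {probe.chromosome}, "
            f"SNP at {snp.chromosome}:{snp.position}"
        )
    offset = snp.position - probe.binding_pos
    return influence_window(probe.strand, probe.design_type).category_of(offset)


DEFAULT_MAF_THRESHOLDS: tuple[float, float] = (0.05, 0.01)


@dataclass
class ProbeAudit:
    """SNP-influence verdict for one probe.

    ``hits`` lists every influential SNP with MAF at or above the smallest
    audit threshold; the per-threshold ``unreliable_at`` map says whether
    any hit reaches that MAF level.
    """

    probe_id: str
    hits: list[tuple[SnpRecord, InfluenceCategory]]
    unreliable_at: dict[float, bool]

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def worst_category(self) -> InfluenceCategory | None:
        if not self.hits:
            return None
        return max((cat for _, cat in self.hits), key=SEVERITY.__getitem__)

    @property
    def unreliable_at_05(self) -> bool:
        return self.unreliable_at.get(0.05, False)

    @property
    def unreliable_at_01(self) -> bool:
        return self.unreliable_at.get(0.01, False)


def audit_probe(
    probe: ProbeRecord,
    snps: Iterable[SnpRecord],
    maf_thresholds: Sequence[float] = DEFAULT_MAF_THRESHOLDS,
) -> ProbeAudit:
    """Audit one probe against a SNP collection.

    SNPs on other chromosomes are ignored (callers may pass the full panel).
    A hit is any SNP inside the probe's influence window with
    ``maf >= min(maf_thresholds)``.
    """
    if not maf_thresholds:
        raise ValueError("need at least one MAF threshold")
    min_t = min(maf_thresholds)
    window = influence_window(probe.strand, probe.design_type)
    hits: list[tuple[SnpRecord, InfluenceCategory]] = []
    for snp in snps:
        if snp.chromosome != probe.chromosome or snp.maf < min_t:
            continue
        cat = window.category_of(snp.position - probe.binding_pos)
        if cat is not None:
            hits.append((snp, cat))
    unreliable = {
        t: any(snp.maf >= t for snp, _ in hits) for t in maf_thresholds
    }
    return ProbeAudit(probe_id=probe.probe_id, hits=hits, unreliable_at=unreliable)


@dataclass
class AuditSummary:
    """Per-threshold probe counts plus genomic-bin histograms.

    For each MAF threshold the ``counts`` entry holds:
    ``onsite``/``nt5``/``nt10`` — probes with >= 1 hit in that window (a
    probe may appear in several); ``multi_within_10nt`` — probes with >= 2
    hits across all three windows; ``multi_within_5nt`` — probes with >= 2
    hits within ONSITE+5nt; ``unreliable`` — probes with >= 1 hit anywhere.
    ``histograms`` maps each threshold to ``{bin_start: n_probes_with_hits}``.
    """

    n_probes: int
    thresholds: tuple[float, ...]
    counts: dict[float, dict[str, int]]
    histograms: dict[float, dict[int, int]]
    bin_width: int = 100_000


def audit_all(
    probes: Sequence[ProbeRecord],
    snps: Iterable[SnpRecord],
    maf_thresholds: Sequence[float] = DEFAULT_MAF_THRESHOLDS,
    bin_width: int = 100_000,
) -> tuple[list[ProbeAudit], AuditSummary]:
    """Audit every probe and summarize counts per MAF threshold.

    Uses a position index over the SNP panel so the cost is
    O(n_probes x window_size + n_snps).
    """
    if not maf_thresholds:
        raise ValueError("need at least one MAF threshold")
    min_t = min(maf_thresholds)
    index: dict[tuple[str, int], list[SnpRecord]] = defaultdict(list)
    for snp in snps:
        if snp.maf >= min_t:
            index[(snp.chromosome, snp.position)].append(snp)

    thresholds = tuple(sorted(maf_thresholds, reverse=True))
    audits: list[ProbeAudit] = []
    counts = {
        t: {
            "onsite": 0,
            "nt5": 0,
            "nt10": 0,
            "multi_within_10nt": 0,
            "multi_within_5nt": 0,
            "unreliable": 0,
        }
        for t in thresholds
    }
    histograms: dict[float, dict[int, int]] = {t: defaultdict(int) for t in thresholds}
    cat_key = {
        InfluenceCategory.ONSITE: "onsite",
        InfluenceCategory.NT5: "nt5",
        InfluenceCategory.NT10: "nt10",
    }
    for probe in probes:
        window = influence_window(probe.strand, probe.design_type)
        hits: list[tuple[SnpRecord, InfluenceCategory]] = []
        for offset in sorted(window.all_offsets):
            for snp in index.get((probe.chromosome, probe.binding_pos + offset), ()):
                hits.append((snp, window.category_of(offset)))
        unreliable = {
            t: any(snp.maf >= t for snp, _ in hits) for t in maf_thresholds
        }
        audits.append(ProbeAudit(probe.probe_id, hits, unreliable))
        for t in thresholds:
            hits_t = [(s, c) for s, c in hits if s.maf >= t]
            if not hits_t:
                continue
            c = counts[t]
            c["unreliable"] += 1
            seen_cats = {cat for _, cat in hits_t}
            for cat in seen_cats:
                c[cat_key[cat]] += 1
            if len(hits_t) >= 2:
                c["multi_within_10nt"] += 1
            n_near = sum(
                1 for _, cat in hits_t
                if cat in (InfluenceCategory.ONSITE, InfluenceCategory.NT5)
            )
            if n_near >= 2:
                c["multi_within_5nt"] += 1
            bin_start = (probe.binding_pos // bin_width) * bin_width
            histograms[t][bin_start] += 1

    summary = AuditSummary(
        n_probes=len(probes),
        thresholds=thresholds,
        counts={t: dict(c) for t, c in counts.items()},
        histograms={t: dict(h) for t, h in histograms.items()},
        bin_width=bin_width,
    )
    return audits, summary


def blocklist_from_audits(audits: Iterable[ProbeAudit], threshold: float) -> list[str]:
    """Probe ids unreliable at ``threshold``, sorted."""
    return sorted(a.probe_id for a in audits if a.unreliable_at.get(threshold, False))


def audits_to_frame(audits: Sequence[ProbeAudit]):
    """Flatten audits into a table (one row per probe) for writing."""
    import pandas as pd

    rows = []
    for a in audits:
        hit_desc = ";".join(
            f"{s.chromosome}:{s.position}:{s.ref_allele}>{s.alt_allele}"
            f":maf={s.maf:.4g}:{c.value}"
            for s, c in sorted(a.hits, key=lambda h: (h[0].position, h[0].alt_allele))
        )
        row = {
            "probe_id": a.probe_id,
            "n_hits": a.n_hits,
            "worst_category": a.worst_category.value if a.worst_category else "",
            "hits": hit_desc,
        }
        for t in sorted(a.unreliable_at, reverse=True):
            row[f"unreliable_at_{t:g}"] = int(a.unreliable_at[t])
        rows.append(row)
    return pd.DataFrame(rows)


def summary_to_frame(summary: AuditSummary):
    """Long-format summary table: one (threshold, metric, value) row each."""
    import pandas as pd

    rows = [{"maf_threshold": "", "metric": "n_probes", "value": summary.n_probes}]
    for t in summary.thresholds:
        for metric, value in summary.counts[t].items():
            rows.append({"maf_threshold": f"{t:g}", "metric": metric, "value": value})
        for bin_start in sorted(summary.histograms[t]):
            rows.append(
                {
                    "maf_threshold": f"{t:g}",
                    "metric": f"hist_{bin_start}",
                    "value": summary.histograms[t][bin_start],
                }
            )
    return pd.DataFrame(rows)
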