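"""Shared fixtures and the independent brute-force influence oracle."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hlameth.io_formats import BetaMatrix, ProbeRecord, SampleInfo, SnpRecord


def make_probe(
    probe_id="cg_test",
    chromosome="6",
    binding_pos=1000,
    strand="F",
    design_type="II",
    **kw,
) -> ProbeRecord:
    return ProbeRecord(probe_id, chromosome, binding_pos, strand, design_type, **kw)


def make_snp(position=1000, maf=0.1, chromosome="6", ref="A", alt="G") -> SnpRecord:
    return SnpRecord(chromosome, position, ref, alt, maf)


def oracle_category(strand: str, design: str, offset: int) -> str | None:
    """Literal transcription of the published per-layout offset ranges.

    Kept deliberately independent of the package's window tables: plain
    if/elif over the quoted ranges, no shared code.
    """
    if strand == "F" and design == "I":
        if offset in (-1, 0):
            return "ONSITE"
        if 1 <= offset <= 5:
            return "5nt"
        if 6 <= offset <= 10:
            return "10nt"
    elif strand == "F" and design == "II":
        if offset == 0:
            return "ONSITE"
        if 1 <= offset <= 5:
            return "5nt"
        if 6 <= offset <= 10:
            return "10nt"
    elif strand == "R" and design == "I":
        if offset in (1, 2):
            return "ONSITE"
        if -4 <= offset <= 0:
            return "5nt"
        if -9 <= offset <= -5:
            return "10nt"
    elif strand == "R" and design == "II":
        if offset == 1:
            return "ONSITE"
        if -4 <= offset <= 0:
            return "5nt"
        if -9 <= offset <= -5:
            return "10nt"
    return None


def make_cohort(n_case=42, n_ctrl=42, carriers_case=42, carriers_ctrl=8):
    samples = []
    for i in range(n_case):
        samples.append(
            SampleInfo(f"case{i:03d}", "case", i < carriers_case, 30.0, "F", 22.0)
        )
    for i in range(n_ctrl):
        samples.append(
            SampleInfo(f"ctrl{i:03d}", "control", i < carriers_ctrl, 30.0, "M", 22.0)
        )
    return samples


def matrix_from_array(values, probe_ids=None, sample_ids=None, **kw) -> BetaMatrix:
    values = np.asarray(values, float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids), **kw)


@pytest.fixture
def cohort():
    return make_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
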