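"""Shared fixtures: a calibrated synthetic cohort (session-scoped, since
several modules test against it) and small hand-traced inputs."""

from __future__ import annotations

import numpy as np
import pytest

from vafshape.io_formats import ClinicalRecord, CNVSegment, MutationRecord
from vafshape.mf_filter import run_filter_chain
from vafshape.shape_params import profile_cohort
from vafshape.synthetic import default_cohort_spec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default five-archetype cohort: n = 500, seed 1."""
    return simulate_cohort(default_cohort_spec(n_samples=500, seed=1))


@pytest.fixture(scope="session")
def cohort_profile(default_cohort):
    """Filter chain + shape parameters of the default cohort."""
    chain = run_filter_chain(
        default_cohort.mutations, default_cohort.segments, default_cohort.clinical
    )
    params, corr = profile_cohort(chain.vafsets.values())
    return {
        "chain": chain,
        "params": params,
        "corr": corr,
        "truth": default_cohort.truth,
    }


def _mut(sample="S1", pos=150, ref="C", alt="T", ref_n=40, alt_n=20,
         polyphen="probably_damaging", gene="TP53", chrom="1"):
    return MutationRecord(
        sample_id=sample, chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        ref_count=ref_n, alt_count=alt_n, polyphen_class=polyphen, gene=gene,
    )


@pytest.fixture
def make_mutation():
    return _mut


@pytest.fixture
def hand_traced_sample():
    """8 mutations engineered so 2 fail depth, 2 fail the MF class, 1 fails
    the copy-neutral rule — exactly 3 VAFs survive.

    Segments: [1, 1000] neutral (mean 0.0, 50 probes); [1001, 2000] altered
    (mean 0.5, 50 probes); [2001, 3000] neutral but under-supported
    (mean 0.1, 5 probes).
    """
    muts = [
        _mut(pos=100, ref_n=10, alt_n=5),               # fails depth (15 < 20)
        _mut(pos=110, ref_n=10, alt_n=9),               # fails depth (19 < 20)
        _mut(pos=120, polyphen="benign"),               # fails MF class
        _mut(pos=130, polyphen="unknown"),              # fails MF class
        _mut(pos=1500),                                 # fails CNV (altered segment)
        _mut(pos=140, ref_n=30, alt_n=10),              # survives: VAF 0.25
        _mut(pos=150, ref_n=20, alt_n=20, polyphen="possibly_damaging"),  # VAF 0.5
        _mut(pos=160, ref_n=10, alt_n=30),              # survives: VAF 0.75
    ]
    segs = [
        CNVSegment("S1", "1", 1, 1000, 50, 0.0),
        CNVSegment("S1", "1", 1001, 2000, 50, 0.5),
        CNVSegment("S1", "1", 2001, 3000, 5, 0.1),
    ]
    clinical = [
        ClinicalRecord(sample_id="S1", cancer_type="TEST", purity=1.0,
                       survival_days=100.0, event=1)
    ]
    return muts, segs, clinical


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
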