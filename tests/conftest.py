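import numpy as np
import pandas as pd
import pytest

import th2screen as t2


@pytest.fixture(scope="session")
def tiny_library():
    rows = [
        ("gA_sg0", "gA", "ACGTACGTACGTACGTACGT", False),
        ("gA_sg1", "gA", "TTTTACGTACGTACGTACGT", False),
        ("gB_sg0", "gB", "CCCCACGTACGTACGTACGT", False),
        ("ctrl_0", "nt", "GGGGACGTACGTACGTACGT", True),
    ]
    return t2.GuideLibrary(
        pd.DataFrame(rows, columns=["guide_id", "gene", "sequence", "is_control"])
    )


@pytest.fixture(scope="session")
def small_screen():
    """Small simulated screen with known truth (fast to fit)."""
    cfg = t2.ScreenSimConfig(
        n_genes=40, guides_per_gene=3, n_controls=10, n_screens=2, seed=11
    )
    return t2.simulate_screen(cfg)


@pytest.fixture(scope="session")
def axis_timecourse():
    """Time course rich enough (6 reps, low noise) for p<1e-10 axis genes."""
    cfg = t2.TimecourseSimConfig(
        n_genes=600, n_replicates=6, noise_sd=0.1, lfc_sd=3.0, seed=21
    )
    return t2.simulate_timecourse(cfg)


@pytest.fixture(scope="session")
def axes(axis_timecourse):
    expr, meta, _ = axis_timecourse
    act = t2.build_axis(expr, meta, "activation")
    diff = t2.build_axis(expr, meta, "differentiation")
    return act, diff


def make_peakset(rows, **labels):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "height"])
    return t2.PeakSet(df, **labels)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
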