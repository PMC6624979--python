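import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from giscreen import SimConfig, simulate_screen
from giscreen.screen_data import ReplicateBinding, SampleLayout, ScreenDesign, _tensor_from_reps

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale screen small enough for repeated fits in unit tests."""
    return simulate_screen(
        SimConfig(
            n_genes=8, guides_per_gene=2, n_controls=2, n_samples=3,
            n_replicates=2, n_lethal=2, seed=11,
        )
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default fixture geometry (25 genes x 3 guides, 4 controls, 6 samples)."""
    return simulate_screen(SimConfig(seed=0))


def make_design(rows, samples=("s1",), n_reps=2, controls=()):
    """Hand-build a ScreenDesign from (construct_id, guide_i, guide_j, gene_g, gene_h) rows."""
    cons = pd.DataFrame(
        rows, columns=["construct_id", "guide_i", "guide_j", "gene_g", "gene_h"]
    ).set_index("construct_id")
    layouts = tuple(
        SampleLayout(
            s,
            tuple(
                ReplicateBinding(str(r + 1), f"{s}_r{r + 1}", ("early",))
                for r in range(n_reps)
            ),
        )
        for s in samples
    )
    return ScreenDesign(cons, layouts, negative_control_genes=frozenset(controls))


def make_lfc(design, D_rep):
    """LFCTensor from a raw (constructs, samples, replicates) array."""
    return _tensor_from_reps(np.asarray(D_rep, dtype=float), design)


@pytest.fixture
def toy_screen_files(tmp_path):
    """Three-construct toy screen on disk: counts, annotation, sample sheet."""
    ann = tmp_path / "annotation.tsv"
    ann.write_text(
        "construct_id\tguide_i\tguide_j\tgene_g\tgene_h\n"
        "c1\tA_1\tN_1\tA\tNC\n"
        "c2\tB_1\tN_1\tB\tNC\n"
        "c3\tA_1\tB_1\tA\tB\n"
    )
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "construct_id\tearly\ts1_r1\ts1_r2\n"
        "c1\t100\t50\t60\n"
        "c2\t100\t200\t180\n"
        "c3\t100\t100\t110\n"
    )
    sheet = tmp_path / "samples.tsv"
    sheet.write_text(
        "column\tsample\treplicate\ttimepoint\n"
        "early\tshared\t1\tearly\n"
        "s1_r1\ts1\t1\tlate\n"
        "s1_r2\ts1\t2\tlate\n"
    )
    return {"counts": counts, "annotation": ann, "samples": sheet}
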