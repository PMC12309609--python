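import numpy as np
import pytest

from kirbind import binding, clustering, simulate
from kirbind.sequences import AlleleSequence

#: alpha-2-helix decoy positions: polymorphic but with a rare minor
#: residue, so panel variance concentrates on the planted signal positions
DECOY_POSITIONS = tuple(range(141, 176))
DECOY_WEIGHTS = {p: (0.92, 0.08) for p in DECOY_POSITIONS}


def make_seq(residues: str, name: str = "A*01:01", locus: str = "A") -> AlleleSequence:
    return AlleleSequence(name=name, locus=locus, residues=residues)


@pytest.fixture
def tiny_panel():
    """Three length-2 alleles for the hand-derived encoding examples."""
    return [
        make_seq("RA", name="A*01:01"),
        make_seq("RG", name="A*02:01"),
        make_seq("SG", name="B*07:02"),
    ]


@pytest.fixture(scope="session")
def planted():
    """Study-scale planted fixture shared by the slower integration tests."""
    panel = simulate.generate_panel(
        97,
        polymorphic_positions=simulate.DEFAULT_SIGNAL_POSITIONS + DECOY_POSITIONS,
        weights_per_position=DECOY_WEIGHTS,
        seed=11,
    )
    model = simulate.default_planted_model(panel, seed=11)
    runs, truth = simulate.generate_binding(panel, model)
    agg = binding.aggregate_replicates(runs)
    log_m = binding.log_transform(agg)
    norm = binding.minmax_per_kir(log_m)
    labels = clustering.BindingClassLabels(class_of=dict(truth))
    return {
        "panel": panel,
        "model": model,
        "runs": runs,
        "truth": truth,
        "log": log_m,
        "norm": norm,
        "labels": labels,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
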