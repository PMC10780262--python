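import pytest
from hypothesis import settings

from dockqm import (
    ParentPeptide,
    QuantitativeMatrix,
    QuantitativeMatrixModel,
    build_saas_library,
)
from dockqm.peptide_library import AMINO_ACIDS, CORE_LABELS
from dockqm.synthetic import sample_ground_truth, simulate_library_scores

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

GLIADIN_SEQ = "QPFPQPELPYP"  # alpha-gliadin 11-mer bound in HLA-DQ2.5
DQ81_SEQ = "SGEGSFQPSQENP"  # 13-mer bound in HLA-DQ8.1; p-1/p11 fixed


@pytest.fixture(scope="session")
def gliadin_parent():
    return ParentPeptide("a-gliadin", GLIADIN_SEQ, core_start=1)


@pytest.fixture(scope="session")
def dq81_parent():
    parent = ParentPeptide("dq81", DQ81_SEQ, core_start=2)
    mutable = tuple(
        pl.label for pl in parent.labels() if pl.label not in ("p-1", "p11")
    )
    return ParentPeptide("dq81", DQ81_SEQ, core_start=2, mutable_labels=mutable)


@pytest.fixture(scope="session")
def gliadin_library(gliadin_parent):
    return build_saas_library(gliadin_parent)


@pytest.fixture(scope="session")
def planted_model(gliadin_parent):
    """Noise-free additive ground truth over the gliadin register."""
    return sample_ground_truth(
        [f"p{i}" for i in range(11)], seed=20240101, delta_spread_kcal=1.0
    )


@pytest.fixture(scope="session")
def planted_scores(planted_model, gliadin_library):
    return simulate_library_scores(planted_model, gliadin_library)


@pytest.fixture(scope="session")
def fitted_core(gliadin_library, planted_scores):
    """Core-mode QM fitted to noise-free planted scores."""
    return QuantitativeMatrixModel(
        gliadin_library, planted_scores, mode="core", allele="HLA-DQ2.5"
    ).fit()


def make_flat_qm(value: float = 0.0, labels=CORE_LABELS) -> QuantitativeMatrix:
    """A hand-built QM with the same contribution everywhere."""
    return QuantitativeMatrix(
        allele="test",
        labels=tuple(labels),
        contributions={(l, aa): value for l in labels for aa in AMINO_ACIDS},
        normalization_mode="core" if tuple(labels) == CORE_LABELS else "custom",
        normalization_mean_kcal=-7.0,
        parent_id="test",
    )


def make_p1_qm(p1_values: dict) -> QuantitativeMatrix:
    """Zero QM except specified contributions at p1 (single-register probes)."""
    contributions = {
        (l, aa): 0.0 for l in CORE_LABELS for aa in AMINO_ACIDS
    }
    for aa, v in p1_values.items():
        contributions[("p1", aa)] = v
    return QuantitativeMatrix(
        allele="test",
        labels=CORE_LABELS,
        contributions=contributions,
        normalization_mode="core",
        normalization_mean_kcal=-7.0,
        parent_id="test",
    )
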