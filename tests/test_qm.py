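"""Quantitative-matrix derivation: normalization, recovery, comparison, IO."""

import numpy as np
import pytest
from scipy import stats

from dockqm import (
    DockingConfig,
    QuantitativeMatrixModel,
    ScoreTable,
    build_qm,
    compare_qms,
    read_qm,
    write_qm,
    UndefinedCorrelationError,
)
from dockqm.peptide_library import AMINO_ACIDS, CORE_LABELS
from dockqm.qm import MODE_LABELS, normalization_set
from dockqm.synthetic import sample_ground_truth, simulate_library_scores

from conftest import make_flat_qm


def constant_scores(lib, value=-7.0):
    return ScoreTable({v.peptide_id: value for v in lib.variants})


class TestBuildQM:
    def test_all_equal_scores_give_zero_matrix(self, gliadin_library):
        qm = build_qm(gliadin_library, constant_scores(gliadin_library), mode="core")
        assert all(c == pytest.approx(0.0) for c in qm.contributions.values())
        qm_wp = build_qm(
            gliadin_library, constant_scores(gliadin_library), mode="whole_peptide"
        )
        assert all(c == pytest.approx(0.0) for c in qm_wp.contributions.values())

    def test_hand_evaluated_contributions(self, gliadin_library):
        # all scores -7.0 except two symmetric core substitutions, so the
        # normalization mean stays exactly -7.0: s/mu - 1 gives +/-0.2
        entries = {v.peptide_id: -7.0 for v in gliadin_library.variants}
        entries["a-gliadin_p4F"] = -8.4
        entries["a-gliadin_p4W"] = -5.6
        qm = build_qm(gliadin_library, ScoreTable(entries), mode="core")
        assert qm.normalization_mean_kcal == pytest.approx(-7.0)
        assert qm.contributions[("p4", "F")] == pytest.approx(0.2)
        assert qm.contributions[("p4", "W")] == pytest.approx(-0.2)
        assert qm.contributions[("p1", "A")] == pytest.approx(0.0)

    @pytest.mark.parametrize("mode,n_expected", [("core", 172), ("whole_peptide", 210)])
    def test_normalization_set_size(self, gliadin_library, mode, n_expected):
        assert len(normalization_set(gliadin_library, MODE_LABELS[mode])) == n_expected

    @pytest.mark.parametrize("mode", ["core", "whole_peptide"])
    def test_mean_zero_identity(self, gliadin_library, planted_scores, mode):
        qm = build_qm(gliadin_library, planted_scores, mode=mode)
        mu = qm.normalization_mean_kcal
        residual = np.mean(
            [
                planted_scores[v.peptide_id] / mu - 1.0
                for v in normalization_set(gliadin_library, qm.labels)
            ]
        )
        assert abs(residual) < 1e-12

    def test_scale_invariance(self, gliadin_library, planted_scores):
        qm1 = build_qm(gliadin_library, planted_scores, mode="core")
        scaled = ScoreTable(
            {k: 3.7 * v for k, v in planted_scores.entries.items()},
            planted_scores.config,
        )
        qm2 = build_qm(gliadin_library, scaled, mode="core")
        for key in qm1.contributions:
            assert qm1.contributions[key] == pytest.approx(
                qm2.contributions[key], abs=1e-12
            )

    def test_monotonicity_lower_affinity_higher_contribution(
        self, gliadin_library, planted_scores, fitted_core
    ):
        qm = fitted_core.qm
        parent = gliadin_library.parent
        for label in qm.labels:
            pairs = []
            for v in gliadin_library.variants:
                if v.substituted_label == label:
                    pairs.append(
                        (planted_scores[v.peptide_id], qm.contributions[(label, v.substituted_aa)])
                    )
            pairs.sort()
            contribs = [c for _, c in pairs]
            assert all(a > b for a, b in zip(contribs, contribs[1:]))

    def test_parent_contribution_identical_across_labels(self, gliadin_library,
                                                         planted_scores):
        qm = build_qm(gliadin_library, planted_scores, mode="core")
        parent = gliadin_library.parent
        wt = {qm.contributions[(l, parent.residue_at(l))] for l in qm.labels}
        assert len(wt) == 1  # known SAAS artefact: one parent affinity reused

    def test_missing_score_rejected_naming_member(self, gliadin_library, planted_scores):
        entries = dict(planted_scores.entries)
        entries.pop("a-gliadin_p4F")
        with pytest.raises(ValueError, match="a-gliadin_p4F"):
            build_qm(gliadin_library, ScoreTable(entries), mode="core")

    def test_zero_mean_rejected(self, gliadin_library):
        entries = {v.peptide_id: 0.0 for v in gliadin_library.variants}
        with pytest.raises(ValueError, match="degenerate"):
            build_qm(gliadin_library, ScoreTable(entries), mode="core")

    def test_core_mode_requires_mutable_core(self, dq81_parent):
        from dockqm import build_saas_library

        lib = build_saas_library(dq81_parent)
        scores = constant_scores(lib)
        build_qm(lib, scores, mode="core")  # p1..p9 mutable: fine
        # whole-peptide mode also fine (p0..p10 mutable); p-1/p11 never covered
        build_qm(lib, scores, mode="whole_peptide")


class TestParameterRecovery:
    def test_noise_free_recovery_is_exact_rank_inversion(
        self, planted_model, fitted_core
    ):
        """Contributions are a strictly decreasing affine map of planted deltas,
        so Spearman correlation is exactly -1 at every covered position."""
        qm = fitted_core.qm
        for label in qm.labels:
            deltas = [planted_model.delta[(label, aa)] for aa in AMINO_ACIDS]
            contribs = [qm.contributions[(label, aa)] for aa in AMINO_ACIDS]
            rho = stats.spearmanr(deltas, contribs).statistic
            assert rho == pytest.approx(-1.0)
            # affine: perfect Pearson anticorrelation too
            assert stats.pearsonr(deltas, contribs).statistic == pytest.approx(-1.0)

    def test_noisy_recovery_rank_correlation(self, gliadin_library):
        model = sample_ground_truth(
            [f"p{i}" for i in range(11)], seed=424242,
            delta_spread_kcal=1.0, noise_sd_kcal=0.1,
        )
        scores = simulate_library_scores(model, gliadin_library)
        qm = build_qm(gliadin_library, scores, mode="core")
        for label in qm.labels:
            deltas = [model.delta[(label, aa)] for aa in AMINO_ACIDS]
            contribs = [qm.contributions[(label, aa)] for aa in AMINO_ACIDS]
            rho = stats.spearmanr(deltas, contribs).statistic
            assert abs(rho) >= 0.9


class TestCompareQMs:
    def test_identical_qms_correlate_perfectly(self, fitted_core):
        r = compare_qms(fitted_core.qm, fitted_core.qm)
        assert all(v == pytest.approx(1.0) for v in r)

    def test_negated_contributions_anticorrelate(self, fitted_core):
        import copy

        other = copy.deepcopy(fitted_core.qm)
        other.contributions = {k: -v for k, v in other.contributions.items()}
        assert compare_qms(fitted_core.qm, other, "p4") == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, fitted_core):
        qm = fitted_core.qm
        x = np.array([qm.contributions[("p4", aa)] for aa in AMINO_ACIDS])
        rng = np.random.default_rng(8)
        y = 0.5 * x + rng.normal(0, 0.1, size=20)
        other = make_flat_qm(0.0)
        for aa, v in zip(AMINO_ACIDS, y):
            other.contributions[("p4", aa)] = float(v)
        # independent textbook formula
        expected = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert compare_qms(qm, other, "p4") == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises_not_silently_zero(self, fitted_core):
        flat = make_flat_qm(0.3)
        with pytest.raises(UndefinedCorrelationError):
            compare_qms(fitted_core.qm, flat, "p4")


class TestQMIO:
    def test_round_trip_full_precision(self, fitted_core, tmp_path):
        path = tmp_path / "qm.csv"
        fitted_core.qm.recommended_cutoff = 0.1
        write_qm(fitted_core.qm, path)
        back = read_qm(path)
        assert back == fitted_core.qm

    def test_missing_residue_column_named(self, fitted_core, tmp_path):
        path = tmp_path / "qm.csv"
        write_qm(fitted_core.qm, path)
        text = path.read_text()
        header_line = next(l for l in text.splitlines() if l.startswith("label,"))
        broken = text.replace(header_line, header_line.replace(",C", ",c2", 1))
        path.write_text(broken)
        with pytest.raises(ValueError, match=r"\['C'\]"):
            read_qm(path)

    def test_mode_label_mismatch_rejected(self, fitted_core, tmp_path):
        path = tmp_path / "qm.csv"
        write_qm(fitted_core.qm, path)
        text = path.read_text().replace(
            "normalization_mode: core", "normalization_mode: whole_peptide"
        )
        path.write_text(text)
        with pytest.raises(ValueError, match="expects labels"):
            read_qm(path)


class TestModelSurface:
    def test_from_files_fit_matches_in_memory(
        self, gliadin_library, planted_scores, fitted_core, tmp_path
    ):
        from dockqm import write_library, write_score_table

        fasta, manifest = tmp_path / "lib.fasta", tmp_path / "lib.csv"
        scores_csv = tmp_path / "scores.csv"
        write_library(gliadin_library, fasta, manifest)
        write_score_table(planted_scores, scores_csv)
        res = QuantitativeMatrixModel.from_files(
            fasta, manifest, scores_csv, mode="core", allele="HLA-DQ2.5"
        ).fit()
        assert res.qm.contributions == fitted_core.qm.contributions

    def test_summary_reports_fit(self, fitted_core):
        text = fitted_core.summary()
        assert "HLA-DQ2.5" in text
        assert "core" in text
        assert "Mean affinity" in text

    def test_alternative_formulas(self, gliadin_library, planted_scores):
        qm_ratio = build_qm(gliadin_library, planted_scores, formula="ratio")
        qm_diff = build_qm(gliadin_library, planted_scores, formula="mu_minus_s")
        mu = qm_ratio.normalization_mean_kcal
        # mu - s = -mu * (s/mu - 1): same ranking, opposite-scale map
        for key in qm_ratio.contributions:
            assert qm_diff.contributions[key] == pytest.approx(
                -mu * qm_ratio.contributions[key], abs=1e-9
            )
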