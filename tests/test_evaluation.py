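import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cleavesite.core import CleavageAnnotation, PeptideHit, ProteinRecord, ValidationError
from cleavesite.evaluation import (
    ConfusionCounts,
    cleavage_density,
    compare_groups,
    evaluate_predictor,
    f1,
    mcc,
    nontryptic_sites,
    precision,
    recall,
    roc_auc,
)
from cleavesite.synthetic import generate_protein, tryptic_digest


class TestMccF1:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(tp=5, tn=5, fp=0, fn=0), 1.0),
            (ConfusionCounts(tp=1, tn=1, fp=1, fn=1), 0.0),
            (ConfusionCounts(tp=2, tn=3, fp=1, fn=1), 5.0 / 12.0),
        ],
    )
    def test_mcc_reference_values(self, counts, expected):
        assert mcc(counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(tp=5, tn=0, fp=0, fn=0), 1.0),
            (ConfusionCounts(tp=0, tn=0, fp=3, fn=2), 0.0),
            (ConfusionCounts(tp=2, tn=0, fp=1, fn=1), 2.0 / 3.0),
        ],
    )
    def test_f1_reference_values(self, counts, expected):
        assert f1(counts) == pytest.approx(expected)

    def test_mcc_zero_marginal_convention(self):
        # no predicted positives: TP+FP = 0 -> MCC defined as 0
        assert mcc(ConfusionCounts(tp=0, tn=5, fp=0, fn=3)) == 0.0

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValidationError):
            mcc(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_against_sklearn_on_random_matrices(self, rng):
        from sklearn.metrics import f1_score, matthews_corrcoef

        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 11, size=4)
            if tp + tn + fp + fn == 0:
                continue
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
            assert mcc(counts) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )
            assert f1(counts) == pytest.approx(
                f1_score(y_true, y_pred, zero_division=0), abs=1e-12
            )


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc, ci = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], n_bootstrap=50)
        assert auc == 1.0
        assert ci[0] <= auc <= ci[1]

    def test_constant_scores_give_half(self):
        _, auc, _ = roc_auc([0.5] * 10, [1] * 5 + [0] * 5, n_bootstrap=50)
        assert auc == pytest.approx(0.5)

    def test_three_of_four_pairs_concordant(self):
        scores = [0.9, 0.4, 0.6, 0.1]
        labels = [1, 1, 0, 0]
        _, auc, _ = roc_auc(scores, labels, n_bootstrap=50)
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.9], [1, 1], n_bootstrap=10)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        curve, _, _ = roc_auc(scores, labels, n_bootstrap=10)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_trapezoid_equals_mann_whitney_pair_counting(self, rng):
        """AUC oracle equivalence on random tied instances."""
        for _ in range(300):
            n = int(rng.integers(4, 21))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            # coarse grid of scores forces ties
            scores = rng.integers(0, 4, n) / 3.0
            _, auc, _ = roc_auc(scores, labels, n_bootstrap=1)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
                pos[:, None] == neg[None, :]
            ).sum()
            assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)

    def test_roc_table_round_trip(self, rng, tmp_path):
        from cleavesite.evaluation import read_roc_table, write_roc_table

        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        curve, _, _ = roc_auc(scores, labels, n_bootstrap=5)
        write_roc_table(curve, tmp_path / "roc.tsv")
        back = read_roc_table(tmp_path / "roc.tsv")
        assert np.allclose(back.fpr, curve.fpr)
        assert np.allclose(back.tpr, curve.tpr)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self, rng):
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        _, auc, ci_a = roc_auc(scores, labels, n_bootstrap=200, seed=4)
        _, _, ci_b = roc_auc(scores, labels, n_bootstrap=200, seed=4)
        assert ci_a == ci_b
        assert ci_a[0] <= auc <= ci_a[1]


class TestNontrypticSites:
    PROTEIN = ProteinRecord(id="P1", sequence="MAKSLNGFAR")

    def test_fully_tryptic_peptide_yields_no_sites(self):
        hits = [PeptideHit("P1", "SLNGFAR")]
        annotations, skipped = nontryptic_sites(hits, [self.PROTEIN])
        assert annotations == [] and skipped == []

    def test_semi_tryptic_peptide_yields_one_site(self):
        hits = [PeptideHit("P1", "LNGFAR")]
        annotations, _ = nontryptic_sites(hits, [self.PROTEIN])
        assert [(a.protein_id, a.p1) for a in annotations] == [("P1", 4)]

    def test_empty_input(self):
        assert nontryptic_sites([], [self.PROTEIN]) == ([], [])

    def test_unmapped_and_ambiguous_peptides_skipped(self):
        protein = ProteinRecord(id="P2", sequence="GGGAAGGGAAGGG")
        hits = [PeptideHit("P2", "WWW"), PeptideHit("P2", "GGGAA")]
        annotations, skipped = nontryptic_sites(hits, [protein])
        assert annotations == []
        assert len(skipped) == 2

    def test_kr_before_pro_boundary_is_nontryptic(self):
        protein = ProteinRecord(id="P3", sequence="AAKPGGG")
        # peptide starting after K3 (followed by P): boundary not tryptic
        hits = [PeptideHit("P3", "PGGG")]
        annotations, _ = nontryptic_sites(hits, [protein])
        assert [(a.protein_id, a.p1) for a in annotations] == [("P3", 3)]

    def test_pure_tryptic_digest_produces_no_sites(self):
        """Consistency with the digest model, incl. missed cleavages."""
        for seed in (1, 2, 3):
            protein = generate_protein(400, seed=seed, protein_id=f"T{seed}")
            for missed in (0, 1, 2):
                hits = tryptic_digest(protein, missed)
                usable = [
                    h for h in hits if protein.sequence.count(h.peptide) == 1
                ]
                annotations, _ = nontryptic_sites(usable, [protein])
                assert annotations == []

    def test_planted_nontryptic_boundaries_recovered(self):
        # internal protease cut inside a tryptic peptide plants two
        # non-tryptic termini
        protein = ProteinRecord(id="P4", sequence="MAKSLNGFARTTTWQK")
        hits = [PeptideHit("P4", "SLNG"), PeptideHit("P4", "FAR")]
        annotations, _ = nontryptic_sites(hits, [protein])
        assert {(a.protein_id, a.p1) for a in annotations} == {("P4", 7)}


class TestCleavageDensity:
    PROTEIN = ProteinRecord(id="P1", sequence="A" * 150)

    def _ann(self, positions):
        return [CleavageAnnotation("MMP9", "P1", p) for p in positions]

    def test_reference_binning(self):
        assert cleavage_density(self._ann([10, 60, 70]), self.PROTEIN, 50) == [1, 2, 0]

    def test_no_sites(self):
        assert cleavage_density([], self.PROTEIN, 50) == [0, 0, 0]

    def test_protein_shorter_than_window(self):
        protein = ProteinRecord(id="P1", sequence="A" * 30)
        assert cleavage_density(self._ann([5, 20]), protein, 50) == [2]

    def test_bin_boundaries(self):
        # p1=50 belongs to bin 0 ([1, 50]), p1=51 to bin 1
        assert cleavage_density(self._ann([50, 51]), self.PROTEIN, 50) == [1, 1, 0]


class TestEvaluatePredictor:
    def _setup(self):
        protein = ProteinRecord(id="P1", sequence="AKAAKAAKAA")
        truth = [CleavageAnnotation("trypsin", "P1", p) for p in (2, 5, 8)]
        return protein, truth

    def test_perfect_scores(self):
        protein, truth = self._setup()
        table = pd.DataFrame(
            {
                "protein_id": ["P1"] * 9,
                "p1": list(range(1, 10)),
                "score": [1.0 if p in (2, 5, 8) else 0.0 for p in range(1, 10)],
            }
        )
        report = evaluate_predictor(table, truth, [protein], "trypsin", n_bootstrap=20)
        assert report.mcc == pytest.approx(1.0)
        assert report.auc == pytest.approx(1.0)
        assert report.n_pos == 3 and report.n_neg == 6

    def test_shuffled_scores_near_half_auc(self, rng):
        protein = generate_protein(2000, seed=5, protein_id="P1")
        from cleavesite.synthetic import rule_sites, trypsin_rule

        sites = rule_sites(protein, trypsin_rule())
        truth = [CleavageAnnotation("trypsin", "P1", p) for p in sites]
        scores = rng.random(protein.length - 1)
        table = pd.DataFrame(
            {
                "protein_id": ["P1"] * (protein.length - 1),
                "p1": list(range(1, protein.length)),
                "score": scores,
            }
        )
        report = evaluate_predictor(table, truth, [protein], "trypsin", n_bootstrap=20)
        assert abs(report.auc - 0.5) < 0.06

    def test_missing_candidates_scored_zero_with_warning(self):
        protein, truth = self._setup()
        table = pd.DataFrame(
            {"protein_id": ["P1"], "p1": [2], "score": [1.0]}
        )
        with pytest.warns(UserWarning, match="missing"):
            report = evaluate_predictor(table, truth, [protein], "trypsin", n_bootstrap=20)
        assert report.recall == pytest.approx(1 / 3)

    def test_no_truth_positives_is_error(self):
        protein, _ = self._setup()
        table = pd.DataFrame({"protein_id": ["P1"], "p1": [2], "score": [1.0]})
        with pytest.raises(ValidationError):
            evaluate_predictor(table, [], [protein], "trypsin")


class TestCompareGroups:
    def test_reference_value(self):
        t, p = compare_groups([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.1909, abs=1e-3)
        assert p == pytest.approx(0.0707, abs=1e-3)

    def test_identical_groups(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_negates_t(self):
        t1, p1 = compare_groups([1, 2, 3, 4], [3, 4, 5, 6])
        t2, p2 = compare_groups([3, 4, 5, 6], [1, 2, 3, 4])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([2.0, 2.0], [2.0, 2.0])

    def test_matches_manual_pooled_formula(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t, p = compare_groups(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_manual = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_manual = 2 * stats.t.sf(abs(t_manual), na + nb - 2)
        assert t == pytest.approx(t_manual)
        assert p == pytest.approx(p_manual)
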