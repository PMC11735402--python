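"""Truth-set metrics, OddsPath, Z', rescaling, signatures, correlation."""

import math

import numpy as np
import pandas as pd
import pytest

import sgescan as sg
from sgescan.evaluation import quadrant_labels, trinucleotide_channel


def brute_force_pr_roc(y, s):
    """Exhaustive threshold sweep oracle for curves and trapezoidal AUCs."""
    thresholds = sorted(set(s), reverse=True)
    pr_pts, roc_pts = [], []
    P, N = sum(y), len(y) - sum(y)
    for t in thresholds:
        pred = [si >= t for si in s]
        tp = sum(p and yi for p, yi in zip(pred, y))
        fp = sum(p and not yi for p, yi in zip(pred, y))
        pr_pts.append((tp / P, tp / (tp + fp) if tp + fp else 1.0))
        roc_pts.append((fp / N, tp / P))
    # prepend the zero-recall / zero-FPR anchors; keep the sweep order so
    # tied blocks stay zero-width vertical steps
    pr_pts.insert(0, (0.0, 1.0))
    roc_pts.insert(0, (0.0, 0.0))
    pr_auc = np.trapezoid([p for _, p in pr_pts], [r for r, _ in pr_pts])
    roc_auc = np.trapezoid([t for _, t in roc_pts], [f for f, _ in roc_pts])
    return float(pr_auc), float(roc_auc)


class TestClassifyFunction:
    def test_strict_zero_threshold(self):
        rfs = pd.Series({"a": 0.8, "b": -0.9, "c": 0.0})
        out = sg.classify_function(rfs)
        assert out.to_dict() == {"a": "abnormal", "b": "normal", "c": "normal"}


class TestConfusionMetrics:
    def test_clinvar_control_counts(self):
        """398/401 pathogenic abnormal, 248/253 benign normal."""
        truth = pd.Series(
            ["pathogenic"] * 401 + ["benign"] * 253,
            index=[f"v{i}" for i in range(654)],
        )
        pred = pd.Series(
            ["abnormal"] * 398 + ["normal"] * 3 + ["abnormal"] * 5 + ["normal"] * 248,
            index=truth.index,
        )
        cm = sg.confusion_metrics(truth, pred)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (398, 3, 5, 248)
        assert cm.precision == pytest.approx(0.988, abs=5e-4)
        assert cm.recall == pytest.approx(0.993, abs=5e-4)
        assert cm.f1 == pytest.approx(0.990, abs=5e-4)

    def test_perfect_classifier(self):
        truth = pd.Series({"a": "pathogenic", "b": "benign"})
        pred = pd.Series({"a": "abnormal", "b": "normal"})
        cm = sg.confusion_metrics(truth, pred)
        assert cm.precision == cm.recall == cm.f1 == 1.0

    def test_no_predicted_positives(self):
        truth = pd.Series({"a": "pathogenic", "b": "benign"})
        pred = pd.Series({"a": "normal", "b": "normal"})
        cm = sg.confusion_metrics(truth, pred)
        assert cm.precision is None
        assert cm.recall == 0.0


class TestPrRoc:
    def test_perfect_separation(self):
        truth = pd.Series(["pathogenic"] * 5 + ["benign"] * 5)
        scores = pd.Series([1.0, 0.9, 0.8, 0.7, 0.6, -0.6, -0.7, -0.8, -0.9, -1.0])
        out = sg.pr_roc(truth, scores)
        assert out["pr_auc"] == pytest.approx(1.0)
        assert out["roc_auc"] == pytest.approx(1.0)

    def test_random_scores_roc_near_half(self):
        rng = np.random.default_rng(0)
        truth = pd.Series(np.where(rng.random(4000) < 0.5, "pathogenic", "benign"))
        scores = pd.Series(rng.normal(size=4000))
        out = sg.pr_roc(truth, scores)
        assert out["roc_auc"] == pytest.approx(0.5, abs=0.05)

    def test_small_example_matches_bruteforce(self):
        y = [1, 0, 1, 1, 0, 0, 1, 0]
        s = [0.9, 0.8, 0.7, 0.7, 0.4, 0.7, 0.2, 0.1]
        truth = pd.Series(["pathogenic" if v else "benign" for v in y])
        out = sg.pr_roc(truth, pd.Series(s))
        pr_auc, roc_auc = brute_force_pr_roc(y, s)
        assert out["roc_auc"] == pytest.approx(roc_auc, abs=1e-12)
        assert out["pr_auc"] == pytest.approx(pr_auc, abs=1e-12)

    def test_random_20_point_inputs_match_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = list((rng.random(20) < 0.4).astype(int))
            if sum(y) in (0, 20):
                continue
            s = list(np.round(rng.normal(size=20), 1))  # force ties
            truth = pd.Series(["pathogenic" if v else "benign" for v in y])
            out = sg.pr_roc(truth, pd.Series(s))
            pr_auc, roc_auc = brute_force_pr_roc(y, s)
            assert out["roc_auc"] == pytest.approx(roc_auc, abs=1e-9)
            assert out["pr_auc"] == pytest.approx(pr_auc, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sg.pr_roc(pd.Series(["benign", "benign"]), pd.Series([0.1, 0.2]))


class TestOddsPath:
    def test_published_control_counts(self):
        out = sg.oddspath(398, 3, 5, 248)
        assert out.ps3 == pytest.approx(50.2, abs=0.05)
        assert out.bs3 == pytest.approx(0.0076, abs=5e-5)
        assert out.ps3_strength == "strong"
        assert out.bs3_strength == "strong"

    def test_uninformative_classifier_gives_one(self):
        # P2 == P1: predicted class independent of truth
        out = sg.oddspath(50, 50, 50, 50)
        assert out.ps3 == pytest.approx(1.0)
        assert out.bs3 == pytest.approx(1.0)

    def test_zero_fp_infinite_without_correction(self):
        out = sg.oddspath(100, 5, 0, 95)
        assert math.isinf(out.ps3)
        corrected = sg.oddspath(100, 5, 0, 95, correction=True)
        assert math.isfinite(corrected.ps3)

    def test_ps3_monotone_in_tp(self):
        values = [sg.oddspath(tp, 100 - tp, 10, 90).ps3 for tp in (60, 75, 90)]
        assert values == sorted(values)

    def test_bs3_monotone_in_fn(self):
        values = [sg.oddspath(100 - fn, fn, 10, 90).bs3 for fn in (2, 5, 10)]
        assert values == sorted(values)


class TestZPrime:
    def test_direct_formula(self):
        rng = np.random.default_rng(0)
        pos = [1.1, 0.9, 1.0, 1.1, 0.9]
        neg = [-1.1, -0.9, -1.0, -1.1, -0.9]
        expected = 1 - 3 * (np.std(pos, ddof=1) + np.std(neg, ddof=1)) / 2.0
        assert sg.z_prime(pos, neg) == pytest.approx(expected)

    def test_tight_controls_approach_one(self):
        assert sg.z_prime([1.0, 1.0 + 1e-9], [-1.0, -1.0 - 1e-9]) == pytest.approx(1.0, abs=1e-6)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError):
            sg.z_prime([1.0, 2.0], [2.0, 1.0])

    def test_simulated_screen_exceeds_half(self, minigene_library, sim_config):
        truth = sg.assign_true_fitness(minigene_library, sim_config)
        counts = sg.simulate_screen(minigene_library, truth, sim_config)
        table = sg.score_screen(counts, minigene_library.to_frame())
        pos = table.loc[table.coding_class == "nonsense", "RFS_median"]
        neg = table.loc[table.coding_class == "synonymous", "RFS_median"]
        assert sg.z_prime(pos, neg) > 0.5


class TestRescaleAndQuadrants:
    def test_external_controls_anchor_exactly(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=200), index=[f"v{i}" for i in range(200)])
        non = {f"v{i}" for i in range(30)}
        syn = {f"v{i}" for i in range(30, 60)}
        out = sg.rescale_external_screen(scores, non, syn)
        assert out.loc[sorted(non), "external_rfs"].median() == pytest.approx(1.0)
        assert out.loc[sorted(syn), "external_rfs"].median() == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "x, y, label",
        [
            (0.5, -0.3, "lower-right"),
            (0.5, 0.3, "upper-right"),
            (-0.5, 0.3, "upper-left"),
            (-0.5, -0.3, "lower-left"),
            (0.0, 0.0, "lower-left"),  # strict-positive boundary rule
        ],
    )
    def test_quadrants(self, x, y, label):
        out = quadrant_labels(pd.Series({"v": x}), pd.Series({"v": y}))
        assert out["v"] == label


class TestSignatureProbability:
    def _signatures(self, channels):
        idx = pd.Index(channels)
        return pd.DataFrame({"SBS1": 0.1, "SBS2": 0.2}, index=idx)

    def test_channel_mapping_with_reverse_complement(self):
        # G>A on the plus strand in context TGC maps to G[C>T]A
        assert trinucleotide_channel("G", "A", "T", "C") == "G[C>T]A"
        assert trinucleotide_channel("C", "T", "G", "A") == "G[C>T]A"

    def test_single_signature_identity(self, toy_model):
        lib = sg.build_library(toy_model, sg.DesignConfig(insertions=False, deletions=False))
        channels = sorted(
            {
                trinucleotide_channel(r.edit.ref, r.edit.alt,
                                      lib.wt_sequences[r.region][r.edit.pos - 1],
                                      lib.wt_sequences[r.region][r.edit.pos + 1])
                for r in lib.records
                if r.edit.kind == "substitution" and len(r.edit.ref) == 1
                and 0 < r.edit.pos < len(lib.wt_sequences[r.region]) - 1
            }
        )
        sigs = pd.DataFrame({"SBS1": np.linspace(0.01, 0.99, len(channels))}, index=channels)
        probs = sg.sbs_mean_probability(lib, sigs, pd.Series({"SBS1": 1.0}))
        rec = next(
            r for r in lib.records
            if r.edit.kind == "substitution" and len(r.edit.ref) == 1
            and 0 < r.edit.pos < len(lib.wt_sequences[r.region]) - 1
        )
        wt = lib.wt_sequences[rec.region]
        ch = trinucleotide_channel(rec.edit.ref, rec.edit.alt, wt[rec.edit.pos - 1], wt[rec.edit.pos + 1])
        assert probs[rec.variant_id] == pytest.approx(sigs.loc[ch, "SBS1"])

    def test_weighted_mean_of_two_signatures(self):
        channels = ["A[C>T]G"]
        sigs = pd.DataFrame({"S1": [0.1], "S2": [0.2]}, index=channels)
        lib = sg.build_library(
            sg.build_transcript_model("ATGACGTAA", [(0, 9)], flank_len=0, constant_len=0),
            sg.DesignConfig(insertions=False, deletions=False, aa_substitutions=False),
        )
        probs = sg.sbs_mean_probability(lib, sigs, pd.Series({"S1": 0.75, "S2": 0.25}))
        # variant C>T at ACG context exists in this sequence (pos 4: A C G)
        hit = probs.dropna()
        assert not hit.empty
        assert hit.iloc[0] == pytest.approx(0.75 * 0.1 + 0.25 * 0.2)

    def test_indels_and_edges_not_applicable(self, toy_model):
        lib = sg.build_library(toy_model)
        sigs = pd.DataFrame({"S1": [0.5]}, index=["A[C>T]G"])
        probs = sg.sbs_mean_probability(lib, sigs, pd.Series({"S1": 1.0}))
        for r in lib.records:
            if r.edit.kind != "substitution":
                assert np.isnan(probs[r.variant_id])


class TestCorrelate:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert sg.correlate(x, x)[0] == pytest.approx(1.0)
        assert sg.correlate(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # ranks of x: 1..5; ranks of y: 2,1,4,3,5 -> rho = 1 - 6*sum(d^2)/(n(n^2-1))
        x = [10.0, 20.0, 30.0, 40.0, 50.0]
        y = [5.0, 1.0, 9.0, 7.0, 11.0]
        d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        assert sg.correlate(x, y)[0] == pytest.approx(1 - 6 * d2 / (5 * 24))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            sg.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
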