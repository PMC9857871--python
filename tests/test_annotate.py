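import numpy as np
import pytest

from spectraqc import (
    SpectralLibrary,
    build_reference_clusters,
    check_label,
    compute_thresholds,
    get_measure,
    qc_library,
    suggest_label,
)

W = np.arange(500, 600, 5.0)
L = W.size


def _blob_library(rng, centers_by_tissue, n=20, sd=0.005):
    """Tissues each drawn as Gaussian blobs around given center spectra."""
    rows, tissues, patients = [], [], []
    for tissue, centers in centers_by_tissue.items():
        for c_idx, center in enumerate(centers):
            for i in range(n):
                rows.append(np.clip(center + rng.normal(0, sd, L), 0.01, None))
                tissues.append(tissue)
                patients.append(f"p{i % 4}")
    return SpectralLibrary(W, rows, tissues, patients)


@pytest.fixture
def two_blob_refs(rng):
    base = 0.3 + 0.2 * np.sin(np.linspace(0, 3, L))
    return (
        _blob_library(
            rng,
            {
                "mucosa": [base, base + 0.15],  # two well-separated blobs
                "serosa": [1.0 - base],
            },
        ),
        base,
    )


class TestClustering:
    def test_two_blobs_recovered(self, two_blob_refs):
        refs, base = two_blob_refs
        model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        centers = model.tissues["mucosa"].centers
        got = sorted(float(c.mean()) for c in centers)
        want = sorted([float(base.mean()), float(base.mean() + 0.15)])
        # blob means recovered within a few noise standard deviations
        np.testing.assert_allclose(got, want, atol=0.01)

    def test_k1_center_is_tissue_mean(self, two_blob_refs):
        refs, _ = two_blob_refs
        model = build_reference_clusters(refs, k=1, name="SAM", seed=0)
        mask = np.array([t == "serosa" for t in refs.tissues])
        np.testing.assert_allclose(
            model.tissues["serosa"].centers[0], refs.reflectance[mask].mean(axis=0)
        )

    def test_deterministic_under_seed(self, two_blob_refs):
        refs, _ = two_blob_refs
        m1 = build_reference_clusters(refs, k=2, name="SAM", seed=7)
        m2 = build_reference_clusters(refs, k=2, name="SAM", seed=7)
        for tissue in m1.tissues:
            np.testing.assert_array_equal(
                m1.tissues[tissue].centers, m2.tissues[tissue].centers
            )
            for a, b in zip(m1.tissues[tissue].members, m2.tissues[tissue].members):
                np.testing.assert_array_equal(a, b)

    def test_too_few_spectra_falls_back_to_k1(self, rng):
        refs = SpectralLibrary(
            W, rng.uniform(0.1, 1, (1, L)), ["rare"], ["p1"]
        )
        with pytest.warns(UserWarning, match="using k=1"):
            model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        assert model.tissues["rare"].centers.shape == (1, L)


class TestThresholds:
    def test_threshold_is_mean_member_measure(self, two_blob_refs):
        refs, _ = two_blob_refs
        model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        thresholds = compute_thresholds(model, refs)
        f = get_measure("SAM")
        for tissue, tc in model.tissues.items():
            for c, (center, idx) in enumerate(zip(tc.centers, tc.members)):
                expected = np.mean([f(center, refs.reflectance[i]) for i in idx])
                assert thresholds[(tissue, c)] == pytest.approx(expected)
                assert thresholds[(tissue, c)] >= 0.0

    def test_identical_members_give_zero_threshold(self):
        s = 0.2 + 0.6 * np.linspace(0, 1, L)
        refs = SpectralLibrary(W, np.tile(s, (5, 1)), ["a"] * 5, ["p1"] * 5)
        model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        thresholds = compute_thresholds(model, refs)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in thresholds.values())

    def test_singleton_cluster_warns(self, rng):
        refs = SpectralLibrary(W, rng.uniform(0.1, 1, (1, L)), ["a"], ["p1"])
        with pytest.warns(UserWarning):
            model = build_reference_clusters(refs, k=1, name="SAM", seed=0)
            thresholds = compute_thresholds(model, refs)
        assert thresholds[("a", 0)] == 0.0


class TestCheckLabel:
    def test_center_with_positive_threshold_confirmed(self, two_blob_refs):
        refs, _ = two_blob_refs
        model = build_reference_clusters(refs, k=1, name="SAM", seed=0)
        thresholds = compute_thresholds(model, refs)
        center = model.tissues["mucosa"].centers[0]
        assert thresholds[("mucosa", 0)] > 0
        d = check_label(center, "mucosa", model, thresholds)
        assert d.verdict == "confirmed"

    def test_far_spectrum_flagged(self, two_blob_refs):
        refs, base = two_blob_refs
        model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        thresholds = compute_thresholds(model, refs)
        d = check_label(1.0 - base, "mucosa", model, thresholds)
        assert d.verdict == "flagged"

    def test_inside_one_cluster_but_beyond_other_is_flagged(self, two_blob_refs):
        # the all-centers rule: membership of one cluster is not enough
        refs, base = two_blob_refs
        model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        thresholds = compute_thresholds(model, refs)
        lo = min(
            range(2),
            key=lambda c: float(model.tissues["mucosa"].centers[c].mean()),
        )
        t = model.tissues["mucosa"].centers[lo]  # dead center of the low blob
        d = check_label(t, "mucosa", model, thresholds)
        values = d.cluster_values
        assert values[("mucosa", lo)] < thresholds[("mucosa", lo)]
        assert d.verdict == "flagged"

    def test_any_center_relaxation_confirms_single_cluster_membership(
        self, two_blob_refs
    ):
        refs, base = two_blob_refs
        model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        thresholds = compute_thresholds(model, refs)
        lo = min(
            range(2),
            key=lambda c: float(model.tissues["mucosa"].centers[c].mean()),
        )
        t = model.tissues["mucosa"].centers[lo]
        strict = check_label(t, "mucosa", model, thresholds, rule="all")
        lenient = check_label(t, "mucosa", model, thresholds, rule="any")
        assert strict.verdict == "flagged"
        assert lenient.verdict == "confirmed"

    def test_unknown_label_errors(self, two_blob_refs):
        refs, base = two_blob_refs
        model = build_reference_clusters(refs, k=1, name="SAM", seed=0)
        thresholds = compute_thresholds(model, refs)
        with pytest.raises(LookupError):
            check_label(base, "bone", model, thresholds)


class TestSuggestLabel:
    def test_center_of_other_tissue_suggested(self, two_blob_refs):
        refs, _ = two_blob_refs
        model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        center = model.tissues["serosa"].centers[0]
        assert suggest_label(center, model) == "serosa"

    def test_argmin_over_all_clusters(self, two_blob_refs):
        refs, base = two_blob_refs
        model = build_reference_clusters(refs, k=2, name="SAM", seed=0)
        assert suggest_label(base, model) == "mucosa"

    def test_invariant_to_duplicated_reference_cluster(self, two_blob_refs, rng):
        refs, base = two_blob_refs
        dup = SpectralLibrary(
            refs.wavelengths,
            np.vstack([refs.reflectance, refs.reflectance]),
            np.concatenate([refs.tissues, refs.tissues]),
            np.concatenate([refs.patients, refs.patients]),
        )
        m1 = build_reference_clusters(refs, k=2, name="SAM", seed=3)
        m2 = build_reference_clusters(dup, k=2, name="SAM", seed=3)
        for t in (base, 1.0 - base, base + 0.07):
            assert suggest_label(t, m1) == suggest_label(t, m2)


class TestQCLibrary:
    def test_mislabeled_targets_flagged_and_relabeled(self, rng):
        base = 0.3 + 0.2 * np.sin(np.linspace(0, 3, L))
        refs = _blob_library(rng, {"mucosa": [base], "serosa": [1.0 - base]}, n=30)
        # targets truly serosa but claimed mucosa
        targets = SpectralLibrary(
            W,
            np.clip((1.0 - base) + rng.normal(0, 0.005, (10, L)), 0.01, None),
            ["mucosa"] * 10,
            ["px"] * 10,
        )
        decisions = qc_library(targets, refs, name="SID-JM-TAN(SAM)", k=2, seed=0)
        assert all(d.verdict == "flagged" for d in decisions)
        assert all(d.suggested == "serosa" for d in decisions)
        assert all(np.isfinite(d.min_value) for d in decisions)

    def test_correct_labels_confirm_more_often_than_wrong_ones(self, suite_library):
        """The strict all-centers rule confirms only a minority of even
        correctly labeled spectra, but wrong labels essentially never
        confirm — the check's asymmetry that makes flagging trustworthy."""
        lib, truth = suite_library
        refs = SpectralLibrary(lib.wavelengths, lib.reflectance, truth, lib.patients)
        decisions = qc_library(lib, refs, name="SID-JM-TAN(SAM)", k=2, seed=11)
        wrong = np.array([c != t for c, t in zip(lib.tissues, truth)])
        confirmed = np.array([d.verdict == "confirmed" for d in decisions])
        rate_correct = confirmed[~wrong].mean()
        rate_wrong = confirmed[wrong].mean()
        assert rate_wrong <= 0.05
        assert rate_correct > rate_wrong + 0.1

    def test_deterministic_decisions(self, rng):
        base = 0.3 + 0.2 * np.sin(np.linspace(0, 3, L))
        refs = _blob_library(rng, {"a": [base], "b": [1.0 - base]}, n=15)
        targets = refs.subset(np.arange(5))
        d1 = qc_library(targets, refs, name="SAM", k=2, seed=9)
        d2 = qc_library(targets, refs, name="SAM", k=2, seed=9)
        assert [(d.verdict, d.suggested) for d in d1] == [
            (d.verdict, d.suggested) for d in d2
        ]
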