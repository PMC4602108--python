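"""Curation, auto-covariance encoding, classifier and network filters."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from floranet import ppi
from floranet.config import ACParams
from floranet.properties import AMINO_ACIDS, standardized_property_matrix


def _record(pid, seq, loc=("C1",)):
    return ppi.ProteinRecord(id=pid, sequence=seq, localizations=frozenset(loc))


def _random_seq(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


# ---------------------------------------------------------------------------
# auto-covariance


def ac_bruteforce(seq: str, lag_max: int = 30) -> np.ndarray:
    """Independent double-loop implementation of the AC descriptor."""
    m = standardized_property_matrix()
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    n = len(seq)
    out = []
    for j in range(7):
        series = [m[j, idx[c]] for c in seq]
        mean = sum(series) / n
        for lag in range(1, lag_max + 1):
            total = 0.0
            for i in range(n - lag):
                total += (series[i] - mean) * (series[i + lag] - mean)
            out.append(total / (n - lag))
    return np.array(out)


class TestACEncode:
    def test_matches_bruteforce_on_random_sequences(self, rng):
        for _ in range(50):
            n = int(rng.integers(40, 160))
            seq = _random_seq(rng, n)
            assert np.max(np.abs(ppi.ac_encode(seq) - ac_bruteforce(seq))) < 1e-10

    def test_homopolymer_encodes_to_zero(self):
        assert np.allclose(ppi.ac_encode("A" * 100), 0.0)

    def test_output_dimensions(self, rng):
        seq = _random_seq(rng, 80)
        assert ppi.ac_encode(seq).shape == (210,)
        assert ppi.encode_pair(_record("a", seq), _record("b", seq)).shape == (420,)

    def test_sequence_shorter_than_lag_window_rejected(self, rng):
        with pytest.raises(ValueError, match="lag window"):
            ppi.ac_encode(_random_seq(rng, 30))

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(ValueError, match="X"):
            ppi.ac_encode("ACDEF" * 10 + "X" + "ACDEF" * 10)

    def test_property_scales_standardized(self):
        m = standardized_property_matrix()
        assert np.allclose(m.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(m.std(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# curation


def nw_identity_oracle(a: str, b: str) -> float:
    """Independent DP for the same objective: maximize alignment score
    (match 1/mismatch 0/gap -1) and, among co-optimal alignments, the
    number of identities. Encoded as a single integer DP on
    score * B + identities with B larger than any identity count."""
    n, m = len(a), len(b)
    B = 10_000
    dp = np.full((n + 1, m + 1), -(10**9), dtype=np.int64)
    dp[0, 0] = 0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = -(10**9)
            if i and j:
                match = 1 if a[i - 1] == b[j - 1] else 0
                best = dp[i - 1, j - 1] + match * B + match
            if i:
                best = max(best, dp[i - 1, j] - B)
            if j:
                best = max(best, dp[i, j - 1] - B)
            dp[i, j] = best
    return int(dp[n, m] % B) / min(n, m)


class TestCuration:
    def _toy(self, rng):
        clean = {f"N{i}": _random_seq(rng, 120) for i in range(6)}
        proteins = {
            "SHORT": _record("SHORT", _random_seq(rng, 49)),
            "OK1": _record("OK1", _random_seq(rng, 100)),
            "UNK": _record("UNK", "ACDEFGHIKX" * 10),
            "DUP_A": _record("DUP_A", "ACDEFGHIKLMNPQRSTVWY" * 5),
            "DUP_B": _record("DUP_B", "ACDEFGHIKLMNPQRSTVWY" * 5),
        }
        proteins.update({k: _record(k, s) for k, s in clean.items()})
        pairs = [
            ("SHORT", "OK1"),      # removed: short partner
            ("UNK", "N0"),         # removed: unknown residue
            ("DUP_A", "N1"),
            ("DUP_B", "N2"),       # removed: DUP_B redundant with DUP_A
            ("N3", "N4"),
            ("N5", "OK1"),
        ]
        return proteins, pairs

    def test_toy_fixture_filters(self, rng):
        proteins, pairs = self._toy(rng)
        curated, report = ppi.curate_positives(pairs, proteins)
        kept = {(a, b) for a, b, _ in curated.pairs}
        assert ("SHORT", "OK1") not in kept
        assert ("UNK", "N0") not in kept
        # exactly one of the duplicated-protein pairs survives
        assert (("DUP_A", "N1") in kept) != (("DUP_B", "N2") in kept)
        assert ("N3", "N4") in kept and ("N5", "OK1") in kept
        assert report["short_or_unknown"] == 2
        assert report["redundant"] == 1

    def test_identity_matches_dp_oracle(self, rng):
        for _ in range(5):
            a = _random_seq(rng, int(rng.integers(40, 90)))
            b = _random_seq(rng, int(rng.integers(40, 90)))
            assert ppi.sequence_identity(a, b) == pytest.approx(
                nw_identity_oracle(a, b), abs=1e-12
            )
        s = _random_seq(rng, 60)
        assert ppi.sequence_identity(s, s) == 1.0

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            curated, report = ppi.curate_positives([], {})
        assert curated.pairs == [] and report["kept"] == 0


class TestNegativeSet:
    def test_disjoint_localization_and_exclusion(self, rng):
        proteins = {}
        for i in range(12):
            comp = "C1" if i < 6 else "C2"
            proteins[f"P{i}"] = _record(f"P{i}", _random_seq(rng, 60), (comp,))
        known = [("P0", "P6"), ("P1", "P7")]
        neg = ppi.build_negative_set(proteins, known, n=10, seed=1)
        known_sets = {frozenset(p) for p in known}
        for a, b, label in neg.pairs:
            assert label == ppi.NEGATIVE
            assert not proteins[a].localizations & proteins[b].localizations
            assert frozenset((a, b)) not in known_sets
        assert len(neg.pairs) == 10

    def test_shared_compartment_everywhere_is_an_error(self, rng):
        proteins = {
            f"P{i}": _record(f"P{i}", _random_seq(rng, 60), ("C1",)) for i in range(5)
        }
        with pytest.raises(ValueError, match="0 eligible"):
            ppi.build_negative_set(proteins, [], n=1, seed=0)

    def test_reports_achievable_maximum(self, rng):
        proteins = {
            "A": _record("A", _random_seq(rng, 60), ("C1",)),
            "B": _record("B", _random_seq(rng, 60), ("C2",)),
        }
        with pytest.raises(ValueError, match="only 1 eligible"):
            ppi.build_negative_set(proteins, [], n=5, seed=0)


class TestAlphaThreshold:
    def test_stated_toy_weights(self):
        thr = ppi.alpha_threshold([1.0, 0.0, 0.0, 0.0, 0.0])
        assert thr.weight_max == 1.0 and thr.weight_min == 0.0
        assert thr.weight_average == pytest.approx(0.2)
        assert thr.alpha == pytest.approx(0.8)

    def test_equal_weights_pass_nothing(self):
        weights = {("a", "b"): 0.4, ("a", "c"): 0.4}
        alpha = ppi.alpha_threshold(list(weights.values())).alpha
        assert alpha == pytest.approx(0.4)
        assert ppi.coexpression_ppi(weights, alpha) == []

    def test_empty_weights_rejected(self):
        with pytest.raises(ValueError):
            ppi.alpha_threshold([])
        with pytest.raises(ValueError):
            ppi.coexpression_ppi({}, 0.5)

    def test_module_preset_overrides(self):
        weights = {("a", "b"): 0.1, ("a", "c"): 0.05, ("a", "d"): 0.2}
        assert ppi.coexpression_ppi(weights, 0.08) == [("a", "b"), ("a", "d")]
        assert ppi.coexpression_ppi(weights, 0.16) == [("a", "d")]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.fractions(0, 1), min_size=1, max_size=20))
    def test_formula_exact_on_binary_rationals(self, fractions):
        weights = [float(f) for f in fractions]
        thr = ppi.alpha_threshold(weights)
        assert thr.alpha == (max(weights) - min(weights)) * 0.6 + float(
            np.mean(weights)
        )


class TestColocalizationFilter:
    def test_intersection_semantics(self, rng):
        proteins = {
            "nuc1": _record("nuc1", _random_seq(rng, 60), ("nucleus",)),
            "nuc2": _record("nuc2", _random_seq(rng, 60), ("nucleus", "cytosol")),
            "chl": _record("chl", _random_seq(rng, 60), ("chloroplast",)),
            "none": ppi.ProteinRecord(id="none", sequence=_random_seq(rng, 60)),
        }
        pairs = [("nuc1", "nuc2"), ("nuc1", "chl"), ("nuc1", "none")]
        kept = ppi.colocalization_filter(pairs, proteins)
        assert kept == [("nuc1", "nuc2")]
        kept_u = ppi.colocalization_filter(pairs, proteins, keep_unannotated=True)
        assert ("nuc1", "none") in kept_u

    def test_subset_and_idempotent(self, rng):
        proteins = {
            f"P{i}": _record(f"P{i}", _random_seq(rng, 60), (f"C{i % 3}",))
            for i in range(8)
        }
        pairs = [(f"P{i}", f"P{j}") for i in range(8) for j in range(i + 1, 8)]
        kept = ppi.colocalization_filter(pairs, proteins)
        assert set(kept) <= set(pairs)
        assert ppi.colocalization_filter(kept, proteins) == kept


class TestClassifier:
    def test_defaults_expose_reported_hyperparameters(self, trained_model):
        _, model = trained_model
        assert model.params.svm_c == 5.278
        assert model.params.svm_gamma == 0.574
        assert model.svc.C == 5.278 and model.svc.gamma == 0.574

    def test_swapped_order_gives_same_prediction(self, corpus, trained_model):
        _, proteins, positives, _ = corpus
        _, model = trained_model
        pairs = positives[:10]
        fwd = model.predict(pairs, proteins)
        rev = model.predict([(b, a) for a, b in pairs], proteins)
        assert list(fwd["label"]) == list(rev["label"])
        assert np.allclose(fwd["score"], rev["score"], atol=1e-9)

    def test_single_class_training_rejected(self, corpus):
        cfg, proteins, positives, _ = corpus
        dataset = ppi.PPIDataset(
            pairs=[(a, b, ppi.POSITIVE) for a, b in positives[:5]]
        )
        with pytest.raises(ValueError, match="both classes"):
            ppi.train_classifier(dataset, proteins)

    def test_training_pairs_separated(self, corpus, trained_model):
        cfg, proteins, _, _ = corpus
        dataset, model = trained_model
        pred = model.predict([(a, b) for a, b, _ in dataset.pairs], proteins)
        labels = np.array([lab for _, _, lab in dataset.pairs])
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(labels, pred["score"]) > 0.95

    def test_duplicate_unordered_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ppi.PPIDataset(pairs=[("a", "b", 1), ("b", "a", 0)])


class TestModuleSubnetwork:
    def test_alpha_override_one_empties_candidates(self, analyzed, corpus, trained_model):
        _, _, partition, _, _, adj = analyzed
        _, proteins, _, _ = corpus
        _, model = trained_model
        top = partition.module_significance.index[0]
        members = partition.members(top)
        with pytest.warns(UserWarning, match="alpha"):
            edges, thr = ppi.module_subnetwork(
                members[:3], members, adj, model, proteins, alpha_override=1.0
            )
        assert len(edges) == 0
        assert thr is not None

    def test_edges_are_colocalized_candidate_pairs(self, tmp_path):
        from floranet.config import PipelineConfig
        from floranet.pipeline import run_all

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_all(PipelineConfig(seed=4), tmp_path / "subnet")
        edges = result.edges
        assert len(edges) > 0
        assert edges["predicted"].all() and edges["colocalized"].all()
        seeds = set(result.report["ppi"]["seed_genes"])
        assert set(edges["seed"]) <= seeds
        # planted interactions dominate the recovered edge set
        tp = sum(
            result.truth.interacts(e.seed, e.candidate) for e in edges.itertuples()
        )
        assert tp / len(edges) >= 0.8
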