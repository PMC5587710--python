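"""96-class catalog, KL-NMF extraction, stability selection, cosine
matching, category summaries, NNLS refitting and YTCA/RTCA attribution."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apobec3kit.signatures import (
    CLASS_LABELS,
    N_CLASSES,
    build_catalog_96,
    class_index,
    correlate_exposure_expression,
    kl_nmf,
    match_to_reference,
    nmf_extract,
    pyrimidine_context,
    refit_exposures_nnls,
    select_signature_number,
    summarize_categories,
    tetranucleotide_attribution,
    toy_reference_catalog,
    BootstrapSignatureNMF,
)
from apobec3kit.signatures.nmf import _kl_divergence
from apobec3kit.sim import build_context_genome, simulate_mutation_set


class TestSubstitutionClasses:
    def test_exactly_96_distinct_labels(self):
        assert len(CLASS_LABELS) == 96
        assert len(set(CLASS_LABELS)) == 96

    def test_index_label_bijection_and_ordering(self):
        seen = set()
        for sub, five, three in itertools.product(
            ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G"), "ACGT", "ACGT"
        ):
            i = class_index(sub, five, three)
            assert CLASS_LABELS[i] == f"{five}[{sub}]{three}"
            seen.add(i)
        assert seen == set(range(96))
        # substitution-major ordering: first block is C>A
        assert all("C>A" in lab for lab in CLASS_LABELS[:16])

    def test_pyrimidine_normalisation(self):
        assert pyrimidine_context("C", "T", "ACA") == ("C>T", "A", "A")
        # G>A at TGT is C>A... reverse complement: ACA with C>T
        assert pyrimidine_context("G", "A", "TGT") == ("C>T", "A", "A")
        with pytest.raises(ValueError, match="inconsistent"):
            pyrimidine_context("C", "T", "AGA")
        with pytest.raises(ValueError, match="not a SNV"):
            pyrimidine_context("C", "C", "ACA")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"), st.sampled_from("ACGT"),
           st.sampled_from("ACGT"))
    def test_strand_normalisation_involution(self, five, ref, three, alt):
        """An SNV and its reverse-complement record map to the same class."""
        from apobec3kit.sim.locus import revcomp

        if ref == alt:
            return
        fwd = pyrimidine_context(ref, alt, five + ref + three)
        rc_ctx = revcomp(five + ref + three)
        rev = pyrimidine_context(revcomp(ref), revcomp(alt), rc_ctx)
        assert fwd == rev


class TestCatalogBuilder:
    def test_hand_enumerated_toy_maf(self):
        records = [
            ("s1", "C", "T", "ACA"),  # A[C>T]A
            ("s1", "C", "T", "ACA"),
            ("s1", "G", "A", "TGT"),  # revcomp -> A[C>T]A
            ("s1", "C", "G", "TCA"),  # T[C>G]A
            ("s1", "T", "C", "ATG"),  # A[T>C]G
            ("s2", "G", "C", "AGT"),  # revcomp ACT -> A[C>G]T
            ("s2", "A", "G", "CAT"),  # revcomp ATG -> A[T>C]G
            ("s2", "C", "A", "GCC"),  # G[C>A]C
            ("s2", "CT", "-", "..."),  # indel, skipped
            ("s2", "C", "T", "AGA"),  # inconsistent context, rejected
        ]
        df = pd.DataFrame(records, columns=["sample", "ref", "alt", "context"])
        df["chrom"], df["pos"] = "chr1", 100
        cat, report = build_catalog_96(df)
        expected = {
            ("s1", class_index("C>T", "A", "A")): 3,
            ("s1", class_index("C>G", "T", "A")): 1,
            ("s1", class_index("T>C", "A", "G")): 1,
            ("s2", class_index("C>G", "A", "T")): 1,
            ("s2", class_index("T>C", "A", "G")): 1,
            ("s2", class_index("C>A", "G", "C")): 1,
        }
        for (s, i), n in expected.items():
            assert cat.loc[CLASS_LABELS[i], s] == n
        assert cat.to_numpy().sum() == sum(expected.values())
        assert report == pytest.approx(
            {**report, "accepted": 8, "skipped_non_snv": 1, "rejected": 1}
        )

    def test_column_sums_equal_accepted_snvs(self, small_cohort):
        cat, report = build_catalog_96(small_cohort.mutations, small_cohort.context_genome)
        assert cat.sum().sum() == report["accepted"]
        pd.testing.assert_frame_equal(cat, small_cohort.truth_catalog, check_dtype=False)


class TestKLNMF:
    def test_objective_non_increasing(self):
        rng = np.random.default_rng(0)
        V = rng.poisson(5.0, size=(96, 20)).astype(float)
        # track divergence across manual restarts of increasing iteration caps
        prev = None
        for iters in (10, 50, 200):
            W, H, d = kl_nmf(V, 3, np.random.default_rng(1), max_iter=iters, tol=0)
            if prev is not None:
                assert d <= prev + 1e-6
            prev = d

    def test_against_sklearn_nmf(self):
        """Independent oracle: sklearn's multiplicative-update KL NMF
        reaches a comparable divergence on the same matrix."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(3)
        truth = toy_reference_catalog()[["SBS2like", "SBS1Alike"]].to_numpy()
        E = rng.uniform(50, 200, size=(2, 30))
        V = rng.poisson(truth @ E).astype(float)
        _, _, d_ours = kl_nmf(V, 2, np.random.default_rng(0), max_iter=5000, tol=1e-10)
        sk = NMF(2, beta_loss="kullback-leibler", solver="mu", init="random",
                 random_state=0, max_iter=5000, tol=1e-10).fit(V)
        d_sk = _kl_divergence(V, sk.transform(V) @ sk.components_)
        assert d_ours <= d_sk * 1.05 + 1.0

    def test_single_signature_recovery_and_k_selection(self):
        rng = np.random.default_rng(7)
        p = toy_reference_catalog()["SBS2like"].to_numpy()
        V = np.column_stack([rng.multinomial(400, p) for _ in range(60)]).astype(float)
        M = pd.DataFrame(V, index=list(CLASS_LABELS))
        sel = select_signature_number(M, range(1, 4), n_bootstraps=15, n_restarts=2, seed=0)
        assert sel.chosen_k == 1
        res = sel.best
        cos = float(
            res.signatures.iloc[:, 0] @ p / np.linalg.norm(res.signatures.iloc[:, 0]) / np.linalg.norm(p)
        )
        assert cos >= 0.99
        assert res.stability.stability >= 0.99

    def test_cutoff_above_one_flags_below_cutoff(self):
        rng = np.random.default_rng(1)
        p = toy_reference_catalog()["SBS5like"].to_numpy()
        V = np.column_stack([rng.multinomial(300, p) for _ in range(20)]).astype(float)
        M = pd.DataFrame(V, index=list(CLASS_LABELS))
        sel = select_signature_number(
            M, [1, 2], stability_cutoff=1.01, n_bootstraps=8, n_restarts=2, seed=0
        )
        assert sel.below_cutoff
        assert sel.chosen_k == int(sel.diagnostics.set_index("k").stability.idxmax())

    def test_invalid_k_rejected(self):
        M = pd.DataFrame(np.ones((96, 3)), index=list(CLASS_LABELS))
        with pytest.raises(ValueError):
            nmf_extract(M, 5, n_bootstraps=2, n_restarts=1)

    def test_estimator_api(self):
        rng = np.random.default_rng(5)
        p = toy_reference_catalog()["SBS2like"].to_numpy()
        X = np.vstack([rng.multinomial(300, p) for _ in range(25)]).astype(float)
        est = BootstrapSignatureNMF(k=1, n_bootstraps=5, n_restarts=2, random_state=0)
        est.fit(X)
        assert est.components_.shape == (1, 96)
        np.testing.assert_allclose(est.components_.sum(axis=1), 1.0, atol=1e-9)
        E = est.transform(X)
        assert E.shape == (25, 1)
        np.testing.assert_allclose(E[:, 0], X.sum(axis=1), rtol=0.1)
        params = est.get_params()
        assert params["n_bootstraps"] == 5


class TestMatchingAndCategories:
    def test_cosine_trivials(self):
        ref = toy_reference_catalog()
        m = match_to_reference(ref[["SBS2like"]], ref)
        assert m.matched.iloc[0] == "SBS2like"
        assert m.cosine.iloc[0] == pytest.approx(1.0)

    def test_disjoint_support_zero_and_hand_value(self):
        u = np.zeros(96); u[0] = 1.0
        v = np.zeros(96); v[1] = 1.0
        w = np.zeros(96); w[:2] = 0.5  # normalized (1,1,0,...)
        ref = pd.DataFrame({"v": v, "w": w}, index=list(CLASS_LABELS))
        P = pd.DataFrame({"u": u}, index=list(CLASS_LABELS))
        sim = match_to_reference(P, ref).attrs["similarity"]
        assert sim.loc["u", "v"] == pytest.approx(0.0, abs=1e-12)
        assert sim.loc["u", "w"] == pytest.approx(1 / np.sqrt(2))

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError, match="96"):
            match_to_reference(pd.DataFrame(np.ones((10, 1))), toy_reference_catalog())

    def test_category_sums(self):
        matches = pd.DataFrame(
            {"extracted": ["e1", "e2"], "matched": ["SBS2like", "SBS1Alike"], "cosine": [1, 1]}
        )
        E = pd.DataFrame([[60.0, 30.0], [40.0, 70.0]], index=["e1", "e2"], columns=["a", "b"])
        per_sample, cohort = summarize_categories(matches, E)
        assert per_sample.loc["a", "APOBEC"] == pytest.approx(0.6)
        assert per_sample.loc["a", "aging"] == pytest.approx(0.4)
        assert per_sample.loc["a", "smoking"] == 0.0
        np.testing.assert_allclose(per_sample.sum(axis=1), 1.0)
        assert cohort["APOBEC"] == pytest.approx(0.5 * 0.6 + 0.5 * 0.3)

    def test_all_apobec_gives_fraction_one(self):
        matches = pd.DataFrame({"extracted": ["e1"], "matched": ["SBS13like"], "cosine": [1.0]})
        E = pd.DataFrame([[10.0, 20.0]], index=["e1"], columns=["a", "b"])
        _, cohort = summarize_categories(matches, E)
        assert cohort["APOBEC"] == pytest.approx(1.0)


class TestNNLSRefit:
    def test_exact_mixture_recovered(self):
        ref = toy_reference_catalog()
        P = ref[["SBS2like", "SBS1Alike", "SBS5like"]]
        E_true = np.array([[100.0, 0.0], [50.0, 80.0], [0.0, 20.0]])
        M = pd.DataFrame(P.to_numpy() @ E_true, index=list(CLASS_LABELS), columns=["a", "b"])
        E = refit_exposures_nnls(M, P)
        np.testing.assert_allclose(E.to_numpy(), E_true, atol=1e-8)
        assert np.all(E.attrs["residual"] < 1e-8)

    def test_single_signature_column(self):
        ref = toy_reference_catalog()
        M = pd.DataFrame(
            100.0 * ref["SBS2like"].to_numpy()[:, None], index=list(CLASS_LABELS), columns=["x"]
        )
        E = refit_exposures_nnls(M, ref[["SBS2like", "SBS13like"]])
        assert E.loc["SBS2like", "x"] == pytest.approx(100.0, abs=1e-6)
        assert E.loc["SBS13like", "x"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_support_search(self):
        """Active-set NNLS equals exhaustive search over sign supports."""
        rng = np.random.default_rng(2)
        P = toy_reference_catalog()[["SBS2like", "SBS1Alike", "SBS5like"]].to_numpy()
        y = P @ np.array([30.0, 0.0, 10.0]) + rng.normal(0, 0.5, 96)
        y = np.maximum(y, 0)
        M = pd.DataFrame(y[:, None], index=list(CLASS_LABELS), columns=["s"])
        E = refit_exposures_nnls(M, pd.DataFrame(P, index=list(CLASS_LABELS)))
        best, best_rss = None, np.inf
        for mask in itertools.product([0, 1], repeat=3):
            idx = [i for i, m in enumerate(mask) if m]
            x = np.zeros(3)
            if idx:
                sol, *_ = np.linalg.lstsq(P[:, idx], y, rcond=None)
                if (sol < -1e-12).any():
                    continue
                x[idx] = sol
            rss = float(((P @ x - y) ** 2).sum())
            if rss < best_rss:
                best_rss, best = rss, x
        np.testing.assert_allclose(E.to_numpy().ravel(), best, atol=1e-6)


class TestTetranucleotideAttribution:
    def _mutations(self, genome_seq, entries):
        rows = []
        for sample, pos1, alt in entries:
            rows.append(
                {"sample": sample, "chrom": "chrT", "pos": pos1, "ref": genome_seq[pos1 - 1],
                 "alt": alt}
            )
        return pd.DataFrame(rows)

    def test_y_and_r_context_classification(self):
        #            123456789012345
        genome = {"chrT": "AATTCATTAGTCAAA"}
        # C at pos 5 in TTCA (Y context), C at pos 12 in GTCA (R context)
        muts = self._mutations(genome["chrT"], [("s1", 5, "T"), ("s1", 12, "T")])
        att = tetranucleotide_attribution(muts, genome)
        assert att.counts.loc["s1", "YTCA"] == 1
        assert att.counts.loc["s1", "RTCA"] == 1
        assert att.counts.loc["s1", "YTCW"] == 1
        assert att.pooled_ytca_rtca == (1, 1)

    def test_non_tcw_mutations_ignored(self):
        genome = {"chrT": "AAGCCGAAAA"}
        muts = self._mutations(genome["chrT"], [("s1", 5, "T")])  # GCC context, not TCW
        att = tetranucleotide_attribution(muts, genome)
        assert att.counts.to_numpy().sum() == 0

    def test_zero_denominator_samples_excluded(self):
        genome = {"chrT": "AATTCATTTTTTTTT"}
        muts = self._mutations(genome["chrT"], [("s1", 5, "T")])  # YTCA only, RTCW = 0
        att = tetranucleotide_attribution(muts, genome)
        assert att.excluded_samples == ["s1"]

    def test_simulation_recovers_yt_fraction(self):
        ref = toy_reference_catalog()[["SBS2like", "SBS13like"]]
        genome = build_context_genome(40000, 21)
        S = 50
        E = pd.DataFrame(
            np.full((2, S), 100.0), index=ref.columns, columns=[f"s{i}" for i in range(S)]
        )
        muts, _ = simulate_mutation_set(ref, E, genome, 0.7, 21)
        att = tetranucleotide_attribution(muts, genome)
        y, r = att.pooled_ytca_rtca
        n = y + r
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(y / n - 0.7) < 3 * se
        assert att.wilcoxon_p < 0.05


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = pd.Series([1, 2, 3, 4, 5.0], index=list("abcde"))
        up = correlate_exposure_expression(x, x**2)
        assert up["rho"] == pytest.approx(1.0)
        dn = correlate_exposure_expression(x, -x)
        assert dn["rho"] == pytest.approx(-1.0)

    def test_hand_rank_formula_n5(self):
        x = pd.Series([3, 1, 4, 1.5, 5], index=list("abcde"))
        y = pd.Series([2, 0.5, 9, 1, 3], index=list("abcde"))
        res = correlate_exposure_expression(x, y)
        rx = x.rank(); ry = y.rank()
        rho_hand = np.corrcoef(rx, ry)[0, 1]
        assert res["rho"] == pytest.approx(rho_hand)

    def test_constant_input_flagged(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        res = correlate_exposure_expression(x, y)
        assert res["constant_input"]

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            correlate_exposure_expression(
                pd.Series([1.0], index=["a"]), pd.Series([2.0], index=["a"])
            )
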