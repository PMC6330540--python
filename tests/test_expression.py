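import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from stemtx import (
    ExpressionMatrix,
    bh_adjust,
    call_dets,
    compute_fpkm,
    ddct_relative_expression,
    det_transcripts,
    kmeans_profiles,
)
from stemtx.expression import standardize_profiles
from stemtx.simulate import simulate_expression

from oracles import brute_bh


def small_expr(counts, zones=("A", "B"), reps=2, lengths=None, libsize=1e6):
    n = len(counts)
    samples = [f"{z}_r{r + 1}" for z in zones for r in range(reps)]
    tids = [f"t{i}" for i in range(n)]
    design = pd.DataFrame(
        {"zone": [s.rsplit("_r", 1)[0] for s in samples],
         "replicate": [1 + i % reps for i in range(len(samples))]},
        index=samples,
    )
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=tids, columns=samples),
        lengths=pd.Series(lengths or [1000.0] * n, index=tids),
        design=design,
        library_sizes=pd.Series([float(libsize)] * len(samples), index=samples),
    )


class TestFpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["a", "b"])
        fpkm = compute_fpkm(
            counts,
            pd.Series([1000.0, 500.0], index=["a", "b"]),
            pd.Series([1e6], index=["s"]),
        )
        assert fpkm.loc["a", "s"] == pytest.approx(10.0)
        assert fpkm.loc["b", "s"] == 0.0

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s": [1]}, index=["a"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series([0.0], index=["a"]),
                         pd.Series([1e6], index=["s"]))

    def test_conservation_identity(self, rng):
        """sum_i fpkm * length * libsize / 1e9 returns the column sums."""
        counts = pd.DataFrame(
            rng.integers(0, 5000, size=(300, 6)).astype(float),
            index=[f"t{i}" for i in range(300)],
            columns=[f"s{j}" for j in range(6)],
        )
        lengths = pd.Series(rng.integers(200, 8000, size=300).astype(float),
                            index=counts.index)
        lib = pd.Series(rng.integers(10**6, 10**7, size=6).astype(float),
                        index=counts.columns)
        fpkm = compute_fpkm(counts, lengths, lib)
        back = fpkm.mul(lengths, axis=0).mul(lib, axis=1) / 1e9
        assert np.allclose(back.sum(axis=0), counts.sum(axis=0), rtol=1e-12)


class TestBH:
    def test_closed_form_triple(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_and_statsmodels(self, rng):
        """Equals both the literal step-up definition and an independent
        library implementation on random vectors, including ties."""
        for _ in range(25):
            n = int(rng.integers(1, 60))
            p = rng.random(n)
            if n > 4:
                p[: n // 3] = p[0]  # force ties
            q = bh_adjust(p)
            assert np.allclose(q, brute_bh(p))
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1])
            assert (q >= p - 1e-15).all()

    def test_monotone_in_p(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDets:
    def test_planted_fold_change_low_noise(self):
        counts = [[400, 410, 390, 100, 101, 99]] * 5 + [[200, 201, 199] * 2] * 5
        expr = small_expr(counts, zones=("A", "B"), reps=3)
        calls = call_dets(expr)
        sub = calls.set_index("transcript_id")
        assert bool(sub.loc["t0", "is_det"])
        assert not bool(sub.loc["t7", "is_det"])

    def test_identical_means_fc_one(self):
        counts = [[50, 50, 50, 50]] * 4
        expr = small_expr(counts)
        calls = call_dets(expr)
        assert np.allclose(calls["fold_change"], 1.0)
        assert not calls["is_det"].any()

    def test_contrast_symmetry(self):
        counts = [[400, 410, 390, 100, 101, 99]] * 6
        expr = small_expr(counts, zones=("A", "B"), reps=3)
        fwd = call_dets(expr, contrasts=[("A", "B")])
        rev = call_dets(expr, contrasts=[("B", "A")])
        assert np.allclose(fwd["fold_change"], 1 / rev["fold_change"])
        assert (fwd["is_det"] == rev["is_det"]).all()

    def test_q_dominates_p(self):
        expr, _ = simulate_expression(300, de_fraction=0.2, seed=81)
        calls = call_dets(expr)
        assert (calls["q"] >= calls["p"] - 1e-15).all()

    def test_supplied_p_table_used_verbatim(self):
        counts = [[400, 410, 390, 100, 101, 99]] * 3
        expr = small_expr(counts, zones=("A", "B"), reps=3)
        sup = pd.DataFrame(
            {"zone_a": "A", "zone_b": "B",
             "transcript_id": [f"t{i}" for i in range(3)],
             "p": [1.0, 1.0, 1.0]}
        )
        calls = call_dets(expr, supplied_p=sup)
        assert not calls["is_det"].any()

    def test_missing_zone_rejected(self):
        expr = small_expr([[1, 1, 1, 1]])
        with pytest.raises(ValueError):
            call_dets(expr, contrasts=[("A", "Z")])

    def test_simulation_sensitivity_and_fdr(self):
        """Planted large effects recovered at the stated thresholds."""
        expr, truth = simulate_expression(
            2000, de_fraction=0.2, dispersion=0.05, seed=82
        )
        det = set(det_transcripts(call_dets(expr)))
        t = truth.expression
        tp = int((t.is_de & t.transcript_id.isin(det)).sum())
        fp = int((~t.is_de & t.transcript_id.isin(det)).sum())
        assert tp / int(t.is_de.sum()) >= 0.9
        assert fp / max(1, len(det)) <= 0.05


class TestKmeans:
    def test_pearson_euclidean_identity(self, rng):
        """On z-scored profiles, squared distance = 2 n (1 - r)."""
        profiles = pd.DataFrame(rng.normal(size=(40, 6)))
        z, _ = standardize_profiles(profiles)
        n = z.shape[1]
        for _ in range(30):
            i, j = rng.integers(0, 40, size=2)
            d2 = float(((z.iloc[i] - z.iloc[j]) ** 2).sum())
            r = float(np.corrcoef(profiles.iloc[i], profiles.iloc[j])[0, 1])
            assert d2 == pytest.approx(2 * n * (1 - r), abs=1e-10)

    def test_identical_groups_separate_perfectly(self):
        a = [1.0, 5.0, 1.0, 1.0]
        b = [5.0, 1.0, 1.0, 5.0]
        profiles = pd.DataFrame([a] * 10 + [b] * 10)
        out = kmeans_profiles(profiles, k=2, seed=0, n_init=10)
        assert out.inertia == pytest.approx(0.0, abs=1e-12)
        assert out.labels.iloc[:10].nunique() == 1
        assert out.labels.iloc[10:].nunique() == 1

    def test_k_one_and_k_too_large(self):
        profiles = pd.DataFrame([[1.0, 2.0, 3.0]] * 5 + [[3.0, 2.0, 1.0]] * 5)
        out = kmeans_profiles(profiles, k=1, seed=0, n_init=5)
        assert set(out.labels) == {1}
        with pytest.raises(ValueError):
            kmeans_profiles(profiles, k=11, seed=0)

    def test_flat_profiles_dropped(self):
        profiles = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
            index=["flat", "up", "down"],
        )
        out = kmeans_profiles(profiles, k=2, seed=0, n_init=5)
        assert out.dropped == ["flat"]
        assert set(out.labels.index) == {"up", "down"}

    def test_deterministic_given_seed(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(60, 6)))
        a = kmeans_profiles(profiles, k=4, seed=3, n_init=10)
        b = kmeans_profiles(profiles, k=4, seed=3, n_init=10)
        assert (a.labels == b.labels).all()

    def test_planted_shapes_recovered(self):
        """Nine planted profile shapes recovered with ARI >= 0.9."""
        expr, truth = simulate_expression(1800, de_fraction=1.0, seed=83)
        out = kmeans_profiles(expr.zone_mean_fpkm(), k=9, seed=0)
        planted = truth.expression.set_index("transcript_id").loc[
            out.labels.index, "cluster"
        ]
        assert adjusted_rand_score(planted, out.labels) >= 0.9


class TestDdct:
    def _table(self):
        rows = []
        ct = {"Apex": {"tub": 20.0, "g": 24.0}, "IN5": {"tub": 20.5, "g": 22.5}}
        for sample, genes in ct.items():
            for gene, v in genes.items():
                rows.append({"sample": sample, "gene": gene, "ct": v})
        return pd.DataFrame(rows)

    def test_calibrator_is_one_and_closed_form(self):
        res = ddct_relative_expression(self._table(), "tub", "Apex")
        res = res.set_index("sample")
        assert res.loc["Apex", "relative_expression"] == pytest.approx(1.0)
        # dCt Apex = 4.0, dCt IN5 = 2.0 -> ddCt = -2 -> F = 4
        assert res.loc["IN5", "relative_expression"] == pytest.approx(4.0)

    def test_missing_reference_rejected(self):
        tab = self._table()
        tab = tab[~((tab["sample"] == "IN5") & (tab["gene"] == "tub"))]
        with pytest.raises(ValueError):
            ddct_relative_expression(tab, "tub", "Apex")

    def test_random_tables_match_formula(self, rng):
        samples = [f"s{i}" for i in range(5)]
        genes = ["ref", "g1", "g2"]
        rows = [
            {"sample": s, "gene": g, "ct": float(rng.uniform(15, 35))}
            for s in samples
            for g in genes
        ]
        tab = pd.DataFrame(rows)
        res = ddct_relative_expression(tab, "ref", "s0")
        wide = tab.pivot(index="sample", columns="gene", values="ct")
        for row in res.itertuples(index=False):
            dct = wide.loc[row.sample, row.gene] - wide.loc[row.sample, "ref"]
            dct0 = wide.loc["s0", row.gene] - wide.loc["s0", "ref"]
            assert row.relative_expression == pytest.approx(2 ** -(dct - dct0))
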