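import itertools

import numpy as np
import pandas as pd
import pytest

from mycoscan import (
    AbundanceTable,
    alpha_diversity,
    bray_curtis,
    pcoa,
    permanova,
)
from mycoscan.community_stats import DistanceMatrix, _permanova_f_r2
from _synth import random_tpm_table


class TestAlphaDiversity:
    def test_uniform_profile(self):
        richness, shannon = alpha_diversity([1] * 8)
        assert richness == 8
        assert shannon == pytest.approx(np.log(8))

    def test_single_taxon(self):
        assert alpha_diversity([0, 5, 0]) == (1, 0.0)

    def test_two_even_taxa(self):
        richness, shannon = alpha_diversity([0.5, 0.5, 0.0])
        assert richness == 2
        assert shannon == pytest.approx(np.log(2))

    def test_all_zero(self):
        assert alpha_diversity([0.0, 0.0]) == (0, 0.0)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = AbundanceTable(
            pd.DataFrame([[5e5, 5e5]] * 2, index=["a", "b"], columns=["t1", "t2"])
        )
        assert bray_curtis(t).values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        t = AbundanceTable(
            pd.DataFrame(
                [[1e6, 0.0], [0.0, 1e6]], index=["a", "b"], columns=["t1", "t2"]
            )
        )
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_sqrt_distance(self):
        # x=(1,0), y=(0.25,0.75) fractions; sqrt -> (1,0) vs (0.5,0.866)
        t = AbundanceTable(
            pd.DataFrame(
                [[1e6, 0.0], [0.25e6, 0.75e6]], index=["a", "b"], columns=["t1", "t2"]
            )
        )
        d = bray_curtis(t, transform="sqrt").values[0, 1]
        assert d == pytest.approx(0.577350, abs=1e-5)

    def test_matches_independent_implementation(self, rng):
        """Cross-check sqrt Bray-Curtis against scikit-bio's beta_diversity."""
        import skbio

        t = random_tpm_table(rng, n_samples=8, n_taxa=12)
        ours = bray_curtis(t, transform="sqrt")
        ref = skbio.diversity.beta_diversity(
            "braycurtis", np.sqrt(t.to_fraction().to_numpy()), ids=t.samples
        )
        np.testing.assert_allclose(ours.values, ref.data, atol=1e-12)

    def test_symmetry_and_range(self, rng):
        t = random_tpm_table(rng, n_samples=10, n_taxa=15, zero_frac=0.3)
        d = bray_curtis(t).values
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_array_equal(d, d.T)


def line_distances(points):
    pts = np.asarray(points, dtype=float)
    d = np.abs(pts[:, None] - pts[None, :])
    return DistanceMatrix(ids=[f"p{i}" for i in range(len(pts))], values=d)


class TestPcoa:
    def test_euclidean_line_reconstructed_exactly(self):
        d = line_distances([0.0, 1.0, 2.0, 3.0])
        res = pcoa(d)
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        recon = np.abs(axis1[:, None] - axis1[None, :])
        np.testing.assert_allclose(recon, d.values, atol=1e-9)

    def test_explained_fractions_valid(self, rng):
        t = random_tpm_table(rng, n_samples=12, n_taxa=20)
        res = pcoa(bray_curtis(t))
        assert (res.explained >= 0).all()
        assert res.explained.sum() <= 1 + 1e-12
        assert (np.diff(res.eigenvalues) <= 1e-12).all()  # sorted desc

    def test_duplicated_sample_coincides(self):
        d = line_distances([0.0, 0.0, 2.0, 5.0])
        res = pcoa(d)
        np.testing.assert_allclose(
            res.coordinates.iloc[0].to_numpy(),
            res.coordinates.iloc[1].to_numpy(),
            atol=1e-9,
        )

    def test_matches_skbio_eigenvalues(self, rng):
        import skbio

        t = random_tpm_table(rng, n_samples=10, n_taxa=15)
        d = bray_curtis(t)
        ours = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.ids), method="eigh"
        )
        k = len(ours.eigenvalues)
        np.testing.assert_allclose(
            ours.eigenvalues, ref.eigvals.to_numpy()[:k], atol=1e-9
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pcoa(line_distances([0.0, 1.0]))


def enumeration_permanova(d2, groups):
    """Oracle: exact permutation distribution by enumerating all distinct
    label assignments."""
    f_obs, r2 = _permanova_f_r2(d2, groups)
    n = len(groups)
    labels = sorted(set(groups))
    n_a = int(np.sum(groups == labels[0]))
    count, total = 0, 0
    for idx_a in itertools.combinations(range(n), n_a):
        perm = np.array([labels[1]] * n, dtype=object)
        perm[list(idx_a)] = labels[0]
        f_perm, _ = _permanova_f_r2(d2, perm)
        count += f_perm >= f_obs
        total += 1
    return f_obs, r2, count / total


class TestPermanova:
    def test_two_collapsed_clusters_r2_one(self):
        d = line_distances([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        labels = pd.Series(list("AAABBB"), index=d.ids)
        with np.errstate(divide="ignore"):
            res = permanova(d, labels, n_perm=99, seed=1)
        assert res.r2 == pytest.approx(1.0)
        assert res.p <= 0.1

    def test_matches_enumeration_oracle(self, rng):
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(ids=[f"s{i}" for i in range(6)], values=d)
        labels = pd.Series(list("AAABBB"), index=dm.ids)
        f_oracle, r2_oracle, p_oracle = enumeration_permanova(d ** 2, labels.to_numpy())
        res = permanova(dm, labels, n_perm=1999, seed=2)
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-12)
        assert res.r2 == pytest.approx(r2_oracle, rel=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=0.06)

    def test_matches_skbio(self, rng):
        import skbio

        t = random_tpm_table(rng, n_samples=14, n_taxa=20)
        d = bray_curtis(t)
        labels = pd.Series(["A"] * 7 + ["B"] * 7, index=d.ids)
        ours = permanova(d, labels, n_perm=99, seed=3)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, ids=d.ids),
            grouping=labels.to_numpy(),
            permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_reordering_invariance_of_statistics(self, rng):
        t = random_tpm_table(rng, n_samples=12, n_taxa=15)
        d = bray_curtis(t)
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=d.ids)
        res1 = permanova(d, labels, n_perm=49, seed=4)
        order = list(reversed(d.ids))
        d2m = DistanceMatrix(
            ids=order,
            values=pd.DataFrame(d.values, index=d.ids, columns=d.ids)
            .loc[order, order]
            .to_numpy(),
        )
        res2 = permanova(d2m, labels, n_perm=49, seed=4)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f, rel=1e-12)
        assert res1.r2 == pytest.approx(res2.r2, rel=1e-12)

    def test_p_never_zero(self):
        d = line_distances([0, 0, 0, 9, 9, 9])
        labels = pd.Series(list("AAABBB"), index=d.ids)
        with np.errstate(divide="ignore"):
            res = permanova(d, labels, n_perm=999, seed=5)
        assert res.p >= 1 / 1000

    def test_singleton_group_rejected(self):
        d = line_distances([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            permanova(d, pd.Series(["A", "B", "B"], index=d.ids), n_perm=9, seed=0)
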