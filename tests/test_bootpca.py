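"""Bootstrap pseudoslices, z-scaling, PCA, orientation, centroids, attractors."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from hemoscape import bootpca as bp
from hemoscape.synthetic_data import CONDITIONS, READOUTS, generate_pools

TOY_READOUTS = READOUTS  # the orientation anchors live in the standard names


def _toy_pools(rng, condition_shifts, pool_size=30):
    """Pools with unit-SD noise and per-(condition, readout) mean shifts."""
    pools = {}
    conditions = tuple(condition_shifts)
    for condition, shifts in condition_shifts.items():
        for j, readout in enumerate(TOY_READOUTS):
            pools[(condition, readout)] = rng.normal(
                shifts[j], 1.0, size=pool_size
            )
    return bp.ReadoutPools(pools=pools, conditions=conditions, readouts=TOY_READOUTS)


def _scaled_matrix_from(values, readouts=None, labels=None):
    readouts = readouts or tuple(f"v{i}" for i in range(values.shape[1]))
    labels = labels if labels is not None else np.array(["x"] * values.shape[0])
    m = bp.PseudosliceMatrix(
        values=np.asarray(values, dtype=float),
        condition_labels=labels,
        readouts=tuple(readouts),
        B=values.shape[0],
    )
    return bp.zscale(m)


def _exact_corr_pair(rng, n, rho):
    """Two columns whose sample correlation is exactly rho (mean 0, sd 1)."""
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)
    z /= z.std(ddof=1)
    y = rho * x + np.sqrt(1 - rho**2) * z
    return np.column_stack([x, y])


class TestPseudoslices:
    def test_design_dimensions(self, preset_pools):
        m = bp.make_pseudoslices(preset_pools, B=250, seed=0)
        assert m.values.shape == (1250, 5)
        assert m.B == 250
        counts = pd.Series(m.condition_labels).value_counts()
        assert (counts == 250).all()
        assert set(counts.index) == set(CONDITIONS)

    def test_seeded_determinism(self, preset_pools):
        a = bp.make_pseudoslices(preset_pools, B=40, seed=5)
        b = bp.make_pseudoslices(preset_pools, B=40, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_degenerate_single_value_pools(self):
        pools = bp.ReadoutPools(
            pools={
                (c, r): np.array([float(hash((c, r)) % 7)])
                for c in CONDITIONS
                for r in READOUTS
            }
        )
        m = bp.make_pseudoslices(pools, B=20, seed=1)
        for condition in CONDITIONS:
            block = m.values[m.condition_labels == condition]
            assert (block == block[0]).all()

    def test_empty_pool_cell_named_in_error(self):
        pools = {(c, r): np.array([1.0]) for c in CONDITIONS for r in READOUTS}
        pools[("Hb", "mda")] = np.array([])
        with pytest.raises(ValueError, match=r"Hb.*mda"):
            bp.ReadoutPools(pools=pools)

    def test_within_condition_draws_are_independent(self, preset_pools):
        m = bp.make_pseudoslices(preset_pools, B=5000, seed=2)
        for condition in CONDITIONS:
            block = m.values[m.condition_labels == condition]
            corr = np.corrcoef(block, rowvar=False)
            off_diag = corr[~np.eye(5, dtype=bool)]
            assert np.abs(off_diag).max() < 0.1


class TestZscale:
    def test_columns_standardized(self, preset_pools):
        scaled = bp.zscale(bp.make_pseudoslices(preset_pools, B=100, seed=3))
        assert np.abs(scaled.values.mean(axis=0)).max() < 1e-9
        assert np.abs(scaled.values.std(axis=0, ddof=1) - 1).max() < 1e-9
        assert scaled.scaled
        assert scaled.column_means is not None

    def test_identity_on_standardized_input(self, rng):
        x = rng.normal(size=(40, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        scaled = _scaled_matrix_from(x)
        np.testing.assert_allclose(scaled.values, x, atol=1e-12)

    def test_double_scaling_rejected(self, preset_pools):
        scaled = bp.zscale(bp.make_pseudoslices(preset_pools, B=20, seed=1))
        with pytest.raises(ValueError, match="already"):
            bp.zscale(scaled)

    def test_zero_variance_column_named(self):
        values = np.random.default_rng(0).normal(size=(20, 5))
        values[:, 2] = 3.14
        m = bp.PseudosliceMatrix(
            values=values,
            condition_labels=np.array(["x"] * 20),
            readouts=READOUTS,
            B=20,
        )
        with pytest.raises(ValueError, match="heme_stress"):
            bp.zscale(m)


class TestRunPca:
    def test_rank_one_input(self, rng):
        x = rng.normal(size=40)
        values = np.column_stack([x, 2 * x + 1])
        result = bp.run_pca(_scaled_matrix_from(values))
        assert result.explained_fraction[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_two_variable_closed_form(self, rng, rho):
        values = _exact_corr_pair(rng, 50, rho)
        result = bp.run_pca(_scaled_matrix_from(values))
        np.testing.assert_allclose(
            result.explained_fraction, [(1 + rho) / 2, (1 - rho) / 2], atol=1e-10
        )

    def test_spectral_properties(self, preset_pools):
        result = bp.run_pca(
            bp.zscale(bp.make_pseudoslices(preset_pools, B=100, seed=7))
        )
        gram = result.loadings.T @ result.loadings
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-9)
        assert result.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(result.explained_fraction) <= 1e-12).all()
        assert (result.explained_fraction >= 0).all()

    def test_matches_covariance_eigendecomposition(self, rng):
        for _ in range(10):
            values = rng.normal(size=(20, 5))
            scaled = _scaled_matrix_from(values)
            result = bp.run_pca(scaled)
            eigenvalues, eigenvectors = linalg.eigh(np.cov(scaled.values, rowvar=False))
            order = np.argsort(eigenvalues)[::-1]
            eigenvalues, eigenvectors = eigenvalues[order], eigenvectors[:, order]
            np.testing.assert_allclose(
                result.explained_fraction, eigenvalues / eigenvalues.sum(), atol=1e-8
            )
            for j in range(5):  # loadings agree up to sign
                dot = abs(eigenvectors[:, j] @ result.loadings[:, j])
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_unscaled_or_thin_input_rejected(self, rng, preset_pools):
        with pytest.raises(ValueError, match="scaled"):
            bp.run_pca(bp.make_pseudoslices(preset_pools, B=10, seed=0))
        thin = _scaled_matrix_from(rng.normal(size=(8, 5)))
        thin = bp.PseudosliceMatrix(
            values=thin.values[:3],
            condition_labels=thin.condition_labels[:3],
            readouts=thin.readouts,
            B=3,
            scaled=True,
        )
        with pytest.raises(ValueError, match="rows"):
            bp.run_pca(thin)


class TestOrientation:
    @pytest.fixture()
    def result(self, preset_pools):
        return bp.run_pca(bp.zscale(bp.make_pseudoslices(preset_pools, B=150, seed=9)))

    def test_anchors_non_negative(self, result):
        oriented = bp.orient_components(result)
        assert oriented.loadings[READOUTS.index("fe58"), 0] >= 0
        assert oriented.loadings[READOUTS.index("heme_metab"), 1] >= 0

    def test_fixed_point(self, result):
        once = bp.orient_components(result)
        twice = bp.orient_components(once)
        np.testing.assert_array_equal(once.loadings, twice.loadings)
        np.testing.assert_array_equal(once.scores, twice.scores)

    def test_involution_after_negation(self, result):
        oriented = bp.orient_components(result)
        flip = np.array([-1, 1, 1, 1, 1])
        negated = bp.PCAResult(
            loadings=oriented.loadings * flip,
            explained_fraction=oriented.explained_fraction,
            scores=oriented.scores * flip,
            readouts=oriented.readouts,
            condition_labels=oriented.condition_labels,
        )
        recovered = bp.orient_components(negated)
        np.testing.assert_allclose(recovered.loadings, oriented.loadings)
        np.testing.assert_allclose(recovered.scores, oriented.scores)

    def test_flips_recorded(self, result):
        oriented = bp.orient_components(result)
        assert set(oriented.orientation) <= {-1, 1}
        for j in (0, 1):
            np.testing.assert_allclose(
                oriented.loadings[:, j],
                result.loadings[:, j] * oriented.orientation[j],
            )


class TestCentroidsAndAttractors:
    def test_grand_centroid_at_origin(self, preset_pools):
        result = bp.run_pca(
            bp.zscale(bp.make_pseudoslices(preset_pools, B=100, seed=4))
        )
        assert np.abs(result.scores.mean(axis=0)).max() < 1e-9

    def test_degenerate_condition_has_zero_width_interval(self, rng):
        shifts = {"Ctrl": np.zeros(5), "Shifted": np.full(5, 2.0)}
        pools = _toy_pools(rng, shifts, pool_size=1)  # single-value pools
        m = bp.make_pseudoslices(pools, B=50, seed=0)
        result = bp.run_pca(bp.zscale(m))
        centroids = bp.condition_centroids(result)
        for _, row in centroids.iterrows():
            assert row["pc1_lo"] == pytest.approx(row["pc1_hi"])

    def test_toxicity_shift_lands_at_positive_pc1(self, rng):
        # damage readouts (fe58, mda, cell_death) shifted far up for one group
        shifts = {
            "Ctrl": np.zeros(5),
            "Tox": np.array([5.0, 5.0, 0.0, 0.0, 5.0]),
        }
        pools = _toy_pools(rng, shifts)
        result = bp.orient_components(
            bp.run_pca(bp.zscale(bp.make_pseudoslices(pools, B=200, seed=1)))
        )
        centroids = bp.condition_centroids(result).set_index("condition")
        assert centroids.loc["Tox", "pc1_mean"] > 0

    def test_unknown_label_rejected(self, preset_pools):
        result = bp.run_pca(bp.zscale(bp.make_pseudoslices(preset_pools, B=20, seed=0)))
        with pytest.raises(ValueError, match="unknown"):
            bp.condition_centroids(result, conditions=("Ctrl", "Hb"))

    @pytest.fixture()
    def toy_states(self, rng):
        # symmetric ±damage pair keeps the damage contrast orthogonal to the
        # metab-only contrast of Adap across condition means; the stress
        # column co-moves with damage so that, after z-scaling, no pure-noise
        # score column is left to mix into PC2
        shifts = {
            "Ctrl": np.zeros(5),
            "Tox": np.array([8.0, 8.0, 4.0, 0.0, 8.0]),
            "Protected": np.array([-8.0, -8.0, -4.0, 0.0, -8.0]),
            "Adap": np.array([0.0, 0.0, 0.0, 8.0, 0.0]),
        }
        pools = _toy_pools(rng, shifts)
        result = bp.orient_components(
            bp.run_pca(bp.zscale(bp.make_pseudoslices(pools, B=200, seed=3)))
        )
        centroids = bp.condition_centroids(result)
        return bp.classify_attractors(centroids, "Ctrl").set_index("condition")

    def test_control_is_baseline(self, toy_states):
        assert toy_states.loc["Ctrl", "state"] == bp.BASELINE

    def test_damage_shift_is_toxic(self, toy_states):
        assert toy_states.loc["Tox", "state"] == bp.TOXIC

    def test_metab_shift_is_adaptive(self, toy_states):
        assert toy_states.loc["Adap", "state"] == bp.ADAPTIVE

    def test_missing_control_rejected(self, preset_pools):
        result = bp.run_pca(bp.zscale(bp.make_pseudoslices(preset_pools, B=20, seed=0)))
        centroids = bp.condition_centroids(result)
        with pytest.raises(ValueError, match="control"):
            bp.classify_attractors(centroids, "NotACondition")


class TestEndToEndStability:
    def test_same_seed_bit_identical_centroids(self, preset_pools):
        def run(seed):
            m = bp.make_pseudoslices(preset_pools, B=250, seed=seed)
            r = bp.orient_components(bp.run_pca(bp.zscale(m)))
            return bp.condition_centroids(r)

        pd.testing.assert_frame_equal(run(17), run(17))

    def test_different_seeds_stay_within_interval_halfwidth(self, preset_pools):
        def run(seed):
            m = bp.make_pseudoslices(preset_pools, B=250, seed=seed)
            r = bp.orient_components(bp.run_pca(bp.zscale(m)))
            return bp.condition_centroids(r).set_index("condition")

        a, b = run(17), run(18)
        halfwidth = (a["pc1_hi"] - a["pc1_lo"]) / 2
        assert (np.abs(a["pc1_mean"] - b["pc1_mean"]) < halfwidth).all()

    def test_preset_structure_echoes_published_biplot(self, preset_pools):
        """Free toxins extreme on the oxidative axis, HbHp on the adaptive
        axis, heme-Hpx nearest control."""
        m = bp.make_pseudoslices(preset_pools, B=250, seed=11)
        result = bp.orient_components(bp.run_pca(bp.zscale(m)))
        loadings = bp.loadings_frame(result)
        signs = np.sign(
            loadings.loc[["fe58", "mda", "cell_death", "heme_stress"], "PC1"]
        )
        assert len(set(signs)) == 1
        assert loadings["PC2"].abs().idxmax() == "heme_metab"
        centroids = bp.condition_centroids(result).set_index("condition")
        assert set(centroids["pc1_mean"].nlargest(2).index) == {"Hb", "HemeAlb"}
        assert centroids["pc2_mean"].idxmax() == "HbHp"
        distance = np.hypot(
            centroids["pc1_mean"] - centroids.loc["Ctrl", "pc1_mean"],
            centroids["pc2_mean"] - centroids.loc["Ctrl", "pc2_mean"],
        ).drop("Ctrl")
        assert distance.idxmin() == "HemeHpx"
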