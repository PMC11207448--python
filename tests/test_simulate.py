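"""Synthetic-panel generator: config defaults, PSD repair, copula recovery."""

import dataclasses

import numpy as np
import pytest

from phenodiv.catalog import DEFAULT_CATALOG, TraitDefinition
from phenodiv.simulate import (
    CorrelationTarget,
    UnknownTraitError,
    build_default_config,
    derive_ratio_traits,
    generate,
    nearest_valid_correlation,
)


class TestDefaultConfig:
    def test_catalog_has_28_traits_with_published_moments(self, default_config):
        assert len(default_config.trait_catalog) == 28
        dbh = default_config.trait_catalog[0]
        assert dbh.abbreviation == "DBH"
        assert dbh.mean == 10.28 and dbh.sd == 1.23
        assert {t.abbreviation for t in default_config.trait_catalog if t.derived} == {
            "WCr", "BLr", "SLA",
        }

    def test_default_panel_and_group_sizes(self, default_config):
        assert default_config.n_accessions == 113
        assert default_config.group_spec.sizes == (54, 26, 25, 8)

    def test_required_anchor_pairs_present(self, default_config):
        got = {
            frozenset((t.trait_a, t.trait_b)): t.rho
            for t in default_config.correlation_targets
        }
        for a, b, rho in [
            ("DBH", "DG", 0.95), ("DBH", "W", 0.95), ("DBH", "CD", 0.95),
            ("DBH", "WCr", -0.50), ("DBH", "Bmc", -0.11), ("TG", "LN", -0.83),
        ]:
            assert got[frozenset((a, b))] == rho

    def test_group_sizes_rescale_to_any_n(self, default_config):
        spec = default_config.group_spec
        for n in (10, 113, 1000, 9999):
            sizes = spec.sizes_for(n)
            assert sum(sizes) == n
        assert spec.sizes_for(113) == (54, 26, 25, 8)


class TestNearestValidCorrelation:
    def test_no_targets_gives_identity(self):
        corr, notes = nearest_valid_correlation([], 5)
        assert np.array_equal(corr, np.eye(5))
        assert notes == []

    def test_single_consistent_target_kept_exactly(self):
        corr, notes = nearest_valid_correlation(
            [CorrelationTarget("A", "B", 0.9)], ("A", "B")
        )
        assert np.allclose(corr, [[1, 0.9], [0.9, 1]])
        assert notes == []

    def test_inconsistent_triple_projected_to_psd(self):
        # rho_AB = rho_BC = 0.9 forces rho_AC >= 0.62; -0.9 is infeasible
        targets = [
            CorrelationTarget("A", "B", 0.9),
            CorrelationTarget("B", "C", 0.9),
            CorrelationTarget("A", "C", -0.9),
        ]
        corr, notes = nearest_valid_correlation(targets, ("A", "B", "C"))
        # independent eigen-decomposition confirms the PSD guarantee
        assert np.linalg.eigvalsh(corr)[0] >= -1e-10
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert notes, "large forced adjustment must be reported"

    def test_default_targets_are_psd_without_projection(self, default_config):
        corr, notes = nearest_valid_correlation(
            default_config.correlation_targets, default_config.trait_names
        )
        assert np.linalg.eigvalsh(corr)[0] >= 0
        assert notes == []

    def test_unknown_trait_is_a_named_error(self):
        with pytest.raises(UnknownTraitError, match="NOPE"):
            nearest_valid_correlation([CorrelationTarget("A", "NOPE", 0.5)], ("A", "B"))


class TestGenerate:
    def test_same_seed_bitwise_identical(self, default_config):
        a = generate(default_config, seed=42)
        b = generate(default_config, seed=42)
        assert np.array_equal(a.values, b.values)
        assert a.accession_ids == b.accession_ids

    def test_zero_sd_collapses_to_mean_vector(self):
        catalog = tuple(
            dataclasses.replace(t, sd=0.0) for t in DEFAULT_CATALOG
        )
        cfg = dataclasses.replace(
            build_default_config(with_groups=False), trait_catalog=catalog,
            correlation_targets=(),
        )
        m = generate(cfg, seed=0)
        means = np.array([t.mean for t in catalog])
        assert np.allclose(m.values, means[None, :])

    def test_moment_recovery_at_large_n(self, big_panel):
        """Sample mean/SD of every trait within 4 standard errors (n=10 000)."""
        n = big_panel.n_accessions
        means = np.array([t.mean for t in big_panel.trait_catalog])
        sds = np.array([t.sd for t in big_panel.trait_catalog])
        se_mean = sds / np.sqrt(n)
        se_sd = sds / np.sqrt(2 * (n - 1))
        assert np.all(np.abs(big_panel.values.mean(0) - means) < 4 * se_mean)
        assert np.all(np.abs(big_panel.values.std(0, ddof=1) - sds) < 4 * se_sd)

    def test_correlation_recovery_at_large_n(self, big_panel, default_config):
        names = list(big_panel.trait_names)
        R = np.corrcoef(big_panel.values, rowvar=False)
        for t in default_config.correlation_targets:
            r = R[names.index(t.trait_a), names.index(t.trait_b)]
            assert abs(r - t.rho) < 0.05, (t.trait_a, t.trait_b, t.rho, r)

    def test_group_offsets_shift_group_means(self):
        cfg = build_default_config(4000)
        m = generate(cfg, seed=3)
        labels = np.array(m.group_labels)
        sla = m.column("SLA")
        # group IV carries the published +65 SLA offset; well separated from I
        assert sla[labels == "IV"].mean() - sla[labels == "I"].mean() > 60
        # and group-level dispersion matches the partitioned within-group SD
        assert sla[labels == "I"].std(ddof=1) < 20

    def test_truncation_containment(self):
        cfg = build_default_config(500, truncate_to_bounds=True)
        m = generate(cfg, seed=5)
        lo = np.array([t.min_bound for t in cfg.trait_catalog])
        hi = np.array([t.max_bound for t in cfg.trait_catalog])
        assert np.all(m.values >= lo) and np.all(m.values <= hi)

    def test_accession_ids_unique(self, panel113):
        assert len(set(panel113.accession_ids)) == 113


class TestDeriveRatioTraits:
    def test_wall_to_cavity_from_published_means(self):
        # wall 10.22 mm, cavity 80.48 mm -> 2*10.22/80.48 = 0.254 (~ published 0.26)
        wcr, _, _, bad = derive_ratio_traits(
            [10.22], [80.48], [1.0], [1.0], [1.0], [1.0]
        )
        assert wcr[0] == pytest.approx(0.254, abs=5e-4)
        assert bad == []

    def test_equal_masses_give_unit_branch_leaf_ratio(self):
        _, blr, _, _ = derive_ratio_traits([1], [1], [2.5], [2.5], [1], [1])
        assert blr[0] == pytest.approx(1.0)

    def test_specific_leaf_area_scale(self):
        # 10 cm² at 0.05 g dry mass -> 200 cm²/g, the published magnitude
        _, _, sla, _ = derive_ratio_traits([1], [1], [1], [1], [10.0], [0.05])
        assert sla[0] == pytest.approx(200.0)

    def test_nonpositive_denominator_yields_error_record(self):
        wcr, blr, sla, bad = derive_ratio_traits(
            [1, 1], [10, 0], [1, 1], [1, 1], [1, 1], [1, 1]
        )
        assert bad == [1]
        assert np.isnan(wcr[1]) and np.isfinite(wcr[0])
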