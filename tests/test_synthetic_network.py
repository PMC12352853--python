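import math

import numpy as np
import pytest

from allomflow import (
    Internode,
    SimulationConfig,
    extract_bifurcations,
    simulate_network,
    sma_fit,
    write_internode_table,
)
from allomflow.exceptions import SimulationError, ValidationError
from allomflow.pipeline import read_internode_table
from allomflow.simulate import internodes_to_frame, load_simulation_config


class TestConfigValidation:
    def test_alpha_must_be_positive(self):
        with pytest.raises(ValidationError):
            SimulationConfig(alpha=0.0)

    def test_radius_ordering(self):
        with pytest.raises(ValidationError):
            SimulationConfig(base_radius=1.0, radius_floor=2.0)

    def test_asymmetry_range(self):
        with pytest.raises(ValidationError):
            SimulationConfig(asymmetry=0.4)
        with pytest.raises(ValidationError):
            SimulationConfig(asymmetry=1.2)

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            SimulationConfig(mode="bogus")


class TestInternodeInvariants:
    def test_positive_dimensions_enforced(self):
        with pytest.raises(ValidationError):
            Internode("T1", "T1.1", None, -5.0, 2.0)
        with pytest.raises(ValidationError):
            Internode("T1", "T1.1", None, 5.0, 0.0)


class TestBranchingCascade:
    def test_zero_noise_symmetric_daughters_exact_half_area(self, cascade_nodes):
        # every bifurcation: daughter radius = parent / sqrt(2), area ratio exactly 1
        by_id = {n.internode_id: n for n in cascade_nodes}
        for node in cascade_nodes:
            if node.parent_id is None:
                continue
            parent = by_id[node.parent_id]
            assert node.diameter == pytest.approx(parent.diameter / math.sqrt(2), abs=0, rel=1e-15)
        for bif in extract_bifurcations(cascade_nodes, min_daughters=2):
            assert bif.area_ratio == pytest.approx(1.0, abs=4e-16)

    def test_count_vs_radius_loglog_slope_minus_two(self, cascade_nodes):
        # level k holds 2^k internodes at radius r0 * 2^(-k/2) => slope -2
        radii = np.array([n.diameter / 2 for n in cascade_nodes])
        levels, counts = np.unique(np.round(np.log10(radii), 9), return_counts=True)
        slope = np.polyfit(levels, np.log10(counts), 1)[0]
        assert slope == pytest.approx(-2.0, abs=1e-8)

    def test_lengths_are_exponential_mean(self):
        cfg = SimulationConfig(base_radius=64.0, radius_floor=1.0, seed=5, length_scale_mu=250.0)
        lengths = np.array([n.length for n in simulate_network(cfg)])
        se = lengths.std(ddof=1) / math.sqrt(lengths.size)
        assert abs(lengths.mean() - 250.0) < 4 * se

    def test_area_conservation_noiseless_sum(self, cascade_nodes):
        for bif in extract_bifurcations(cascade_nodes, min_daughters=2):
            assert sum(r * r for r in bif.daughter_radii) == pytest.approx(
                bif.parent_radius**2, rel=1e-14
            )

    def test_noisy_grand_mean_ratio_within_3_mc_se(self, noisy_cascade_nodes):
        # restrict to bifurcations whose parent is far enough above the floor
        # that daughter truncation is impossible, so measured ratios are
        # unbiased draws of the mean-one split noise
        bifs = [
            b
            for b in extract_bifurcations(noisy_cascade_nodes, min_daughters=2)
            if b.parent_radius >= 3 * 0.8
        ]
        ratios = np.array([b.area_ratio for b in bifs])
        assert ratios.size > 200
        se = ratios.std(ddof=1) / math.sqrt(ratios.size)
        assert abs(ratios.mean() - 1.0) <= 3 * se

    def test_runaway_cap_aborts(self):
        cfg = SimulationConfig(base_radius=64.0, radius_floor=1.0, seed=0, max_internodes=100)
        with pytest.raises(SimulationError, match="max_internodes"):
            simulate_network(cfg)


class TestAllometricCoupling:
    def test_noiseless_alpha2_sma_slope_exactly_two(self):
        cfg = SimulationConfig(
            mode="allometric_coupling", alpha=2.0, base_radius=20.0, radius_floor=1.0, seed=2
        )
        nodes = simulate_network(cfg)
        d = np.array([n.diameter for n in nodes])
        length = np.array([n.length for n in nodes])
        fit = sma_fit(d, length)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [2.0 / 3.0, 1.0, 2.0])
    def test_parameter_recovery_within_own_ci(self, alpha):
        # low coupling noise keeps the SMA one-sided-noise bias well inside
        # the CI width at n ~ 500; expect >= 90% coverage of the true alpha
        hits = 0
        reps = 30
        for rep in range(reps):
            cfg = SimulationConfig(
                mode="allometric_coupling",
                alpha=alpha,
                base_radius=12.0,
                radius_floor=1.0,
                asymmetry=0.6,
                ratio_noise_sd0=0.15,
                coupling_sd=0.005,
                seed=1000 + rep,
                n_trees=4,
            )
            nodes = simulate_network(cfg)
            d = np.array([n.diameter for n in nodes])
            length = np.array([n.length for n in nodes])
            fit = sma_fit(d, length)
            if fit.slope_ci_low <= alpha <= fit.slope_ci_high:
                hits += 1
        assert hits >= 0.9 * reps

    def test_blend_lowers_basal_exponent(self):
        cfg = SimulationConfig(
            mode="allometric_coupling",
            alpha=2.0,
            base_radius=64.0,
            radius_floor=0.8,
            seed=9,
            elastic_blend_radius=8.0,
            elastic_blend_width=0.25,
        )
        nodes = simulate_network(cfg)
        big = [n for n in nodes if n.diameter / 2 >= 32.0]  # far above the blend radius
        small = [n for n in nodes if n.diameter / 2 <= 2.9]  # far below it
        slopes = {}
        for name, subset in (("big", big), ("small", small)):
            d = np.log10([n.diameter for n in subset])
            length = np.log10([n.length for n in subset])
            slopes[name] = np.polyfit(d, length, 1)[0]
        # basal branches approach elastic similarity, distal ones stay near alpha
        assert slopes["big"] == pytest.approx(2 / 3, abs=0.15)
        assert slopes["small"] == pytest.approx(2.0, abs=0.15)
        assert slopes["small"] > slopes["big"]


class TestDeterminism:
    def test_identical_seed_bit_identical_table(self, tmp_path):
        cfg = SimulationConfig(base_radius=30.0, radius_floor=1.0, seed=42, ratio_noise_sd0=0.2)
        a = internodes_to_frame(simulate_network(cfg))
        b = internodes_to_frame(simulate_network(cfg))
        assert a.equals(b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_internode_table(simulate_network(cfg), pa)
        write_internode_table(simulate_network(cfg), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(base_radius=30.0, radius_floor=1.0, seed=1, ratio_noise_sd0=0.2)
        a = internodes_to_frame(simulate_network(cfg))
        b = internodes_to_frame(simulate_network(cfg.with_seed(2)))
        assert not a.equals(b)


class TestTableIO:
    def test_single_internode_two_line_file(self, tmp_path):
        path = tmp_path / "one.csv"
        write_internode_table([Internode("T1", "T1.1", None, 150.0, 3.0)], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0] == "tree_id,internode_id,parent_id,length_mm,diameter_mm"

    def test_write_read_write_byte_identical(self, tmp_path, noisy_cascade_nodes):
        p1 = tmp_path / "t1.csv"
        p2 = tmp_path / "t2.csv"
        write_internode_table(noisy_cascade_nodes, p1)
        write_internode_table(read_internode_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_row_count_conserved(self, tmp_path, noisy_cascade_nodes):
        path = tmp_path / "sim.csv"
        write_internode_table(noisy_cascade_nodes, path)
        assert len(read_internode_table(path)) == len(noisy_cascade_nodes)

    def test_empty_collection_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_internode_table([], tmp_path / "x.csv")


class TestConfigFile:
    def test_yaml_and_json_round_trip(self, tmp_path):
        ypath = tmp_path / "sim.yaml"
        ypath.write_text("mode: branching_cascade\nbase_radius: 16.0\nradius_floor: 1.0\nseed: 7\n")
        cfg = load_simulation_config(ypath)
        assert cfg.base_radius == 16.0 and cfg.seed == 7
        jpath = tmp_path / "sim.json"
        jpath.write_text('{"mode": "branching_cascade", "base_radius": 16.0, "radius_floor": 1.0}')
        assert load_simulation_config(jpath).base_radius == 16.0

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("bogus_field: 1\n")
        with pytest.raises(ValidationError, match="bogus_field"):
            load_simulation_config(path)
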