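"""Virtual chamber execution: mass ledger, patterning, wash-off,
lift-off/collection, hybridization, and swelling kinetics."""

import math

import numpy as np
import pytest

from mapdh.config import RunConfig, SimulationConfig, SwellingConfig
from mapdh.errors import ExecutionError, InvalidParameterError, UnknownStrandError
from mapdh.experiments import (
    characterization_protocol,
    liftoff_collection_experiment,
    quench_architecture_protocol,
)
from mapdh.instrument import (
    ChamberState,
    add_swelling_signal,
    advance_time,
    domain_edge_lengths,
    domain_strain,
    execute,
    hybridize,
    state_snapshot,
)
from mapdh.protocol import (
    Collect,
    Dissolve,
    Flow,
    InkSpec,
    Pattern,
    Protocol,
    StrandSpec,
    Wash,
    make_rect_mask,
)


class TestExecute:
    def test_characterization_run_produces_sixty_attached_domains(self):
        state, events = execute(characterization_protocol(), seed=0)
        assert len(state.domains) == 60
        assert all(d.attached for d in state.domains)
        # vials 1-4 all share one ink here; sizes are uniform
        assert {d.width0_um for d in state.domains} == {50.0}
        assert sum(1 for e in events if e["op"] == "PATTERN") == 60

    def test_mass_ledger(self):
        p = characterization_protocol()
        config = RunConfig()
        state, _ = execute(p, seed=0, config=config)
        rate = config.simulation.flow_rate_ul_s
        for vial in p.vials:
            flowed = sum(
                c.duration_s for c in p.commands
                if c.op == "FLOW" and c.vial_id == vial.vial_id
            )
            assert state.vials[vial.vial_id] == pytest.approx(
                vial.volume_ul - rate * flowed
            )

    def test_pattern_with_wrong_chamber_content_fails(self):
        p = Protocol(
            commands=[Wash(duration_s=1), Pattern(mask_ref="sq", exposure_s=1)],
            vials=[InkSpec(vial_id=1, volume_ul=150.0)],
            masks={"sq": make_rect_mask(50, 50, name="sq")},
        )
        # validation already rejects this grammar; execute refuses too
        with pytest.raises(ExecutionError):
            execute(p, seed=0)

    def test_flow_from_depleted_vial_fails(self):
        p = Protocol(
            commands=[Flow(vial_id=1, duration_s=200.0),
                      Flow(vial_id=1, duration_s=200.0)],
            vials=[InkSpec(vial_id=1, volume_ul=300.0)],
        )
        with pytest.raises(ExecutionError, match="holds"):
            execute(p, seed=0)

    def test_execution_deterministic_per_seed(self):
        cfg = RunConfig(simulation=SimulationConfig(p_washoff=0.3, p_collect=0.5))
        runs = [
            liftoff_collection_experiment(seed=11, config=cfg) for _ in range(2)
        ]
        assert runs[0]["n_lost_before_liftoff"] == runs[1]["n_lost_before_liftoff"]
        assert runs[0]["n_collected"] == runs[1]["n_collected"]
        snaps = [state_snapshot(r["state"]) for r in runs]
        assert snaps[0] == snaps[1]

    def test_dissolve_requires_sacrificial_layer(self):
        p = Protocol(commands=[Dissolve()], vials=[])
        with pytest.raises(ExecutionError, match="sacrificial"):
            execute(p, seed=0, sacrificial=False)

    def test_dissolve_then_collect_recovers_all_with_unit_probability(self):
        out = liftoff_collection_experiment(
            seed=2, config=RunConfig()  # p_washoff 0, p_collect 1
        )
        assert out["n_lost_before_liftoff"] == 0
        assert out["n_collected"] == out["n_architectures"] == 25

    def test_washoff_calibration_matches_observed_loss_rate(self):
        """With p_washoff = 0.25 per multi-round wash exposure, about half
        of 25 three-domain architectures (observed: 12) are lost before
        lift-off; the mean over seeds must sit within binomial sampling
        error of that count."""
        cfg = RunConfig(simulation=SimulationConfig(p_washoff=0.25))
        losses = [
            liftoff_collection_experiment(seed=s, config=cfg)["n_lost_before_liftoff"]
            for s in range(20)
        ]
        mean_frac = np.mean(losses) / 25.0
        # model expectation 1-(1-0.25)^2 = 0.4375; observed 12/25 = 0.48;
        # single-run binomial sd ~ 0.10
        assert abs(mean_frac - 12 / 25) < 0.10
        assert abs(mean_frac - (1 - 0.75**2)) < 0.05

    def test_overlapping_domains_constrain_facing_edges(self):
        from mapdh.experiments import multi_domain_swelling_experiment

        res = multi_domain_swelling_experiment(seed=0, checkpoint_hours=(0.0, 1.0))
        red, green, blue = res.state.domains
        assert red.constrained_edges == {"right"}
        assert green.constrained_edges == {"left", "right"}
        assert blue.constrained_edges == {"left"}


class TestHybridization:
    @pytest.fixture()
    def quenched_state(self):
        state, _ = execute(quench_architecture_protocol(), seed=0)
        return state

    def test_only_complement_bearing_domains_quench(self, quenched_state):
        circle, triangle, plus, square = quenched_state.domains
        assert circle.quenched_fraction["5Acry_3Cy3_R1"] > 0.99
        assert square.quenched_fraction["5Acry_3Cy3_R1"] > 0.99
        # strands in other domains (and the square's other strands) untouched
        assert triangle.quenched_fraction["5Acry_3ATTO488_polyT10"] == 0.0
        assert plus.quenched_fraction["5Acry_3TYE665_polyT10"] == 0.0
        assert square.quenched_fraction["5Acry_3ATTO488_polyT10"] == 0.0
        assert square.quenched_fraction["5Acry_3TYE665_polyT10"] == 0.0

    def test_strand_without_table_entry_rejected(self):
        state = ChamberState(vials={})
        with pytest.raises(UnknownStrandError):
            hybridize(state, "no_such_strand", 100.0, 1.0, RunConfig())

    def test_known_strand_with_absent_complement_is_noop(self):
        state, _ = execute(quench_architecture_protocol(include_quench_step=False),
                           seed=0)
        before = [dict(d.quenched_fraction) for d in state.domains]
        # 5Acry_3Cy3_R1 free in solution targets 5Q_R1', anchored nowhere
        hybridize(state, "5Acry_3Cy3_R1", 500.0, 1.0, RunConfig())
        assert [dict(d.quenched_fraction) for d in state.domains] == before

    def test_quenching_saturates_to_one(self):
        state, _ = execute(quench_architecture_protocol(include_quench_step=False),
                           seed=0)
        hybridize(state, "5Q_R1'", 500.0, 1000.0, RunConfig())
        assert state.domains[0].quenched_fraction["5Acry_3Cy3_R1"] == pytest.approx(
            1.0, abs=1e-12
        )


class TestSwelling:
    def make_state(self, crosslink="S1", constrained=()):
        from mapdh.instrument import HydrogelDomain

        d = HydrogelDomain(
            domain_id=0, center_x_um=0, center_y_um=0,
            width0_um=200.0, height0_um=200.0,
            composition={"x": 100.0}, crosslink_system=crosslink,
            constrained_edges=set(constrained), status="collected",
        )
        return ChamberState(vials={}), d

    def test_no_signal_no_swelling(self):
        cfg = RunConfig()
        state, d = self.make_state()
        state.domains = [d]
        advance_time(state, 60.0, cfg)
        assert domain_strain(d, state, cfg) == 0.0
        assert d.L_um == 200.0

    def test_saturating_exponential_approach(self):
        cfg = RunConfig()
        state, d = self.make_state()
        state.domains = [d]
        add_swelling_signal(state, "S1", cfg)
        strains = []
        for _ in range(10):
            advance_time(state, 6.0, cfg)
            strains.append(domain_strain(d, state, cfg))
        assert strains == sorted(strains)  # monotone nondecreasing
        assert strains[-1] <= cfg.swelling.amplitude["S1"]
        expected = 0.51 * (1 - math.exp(-60.0 / 8.0))
        assert strains[-1] == pytest.approx(expected, rel=1e-9)

    def test_non_crosslinked_domain_is_fixed_point(self):
        cfg = RunConfig()
        state, d = self.make_state(crosslink=None)
        state.domains = [d]
        add_swelling_signal(state, "S1", cfg)
        advance_time(state, 100.0, cfg)
        assert d.L_um == 200.0

    def test_signal_system_mismatch_does_not_swell(self):
        cfg = RunConfig()
        state, d = self.make_state(crosslink="S2")
        state.domains = [d]
        add_swelling_signal(state, "S1", cfg)
        advance_time(state, 100.0, cfg)
        assert domain_strain(d, state, cfg) == 0.0

    def test_constrained_edge_swells_at_half_rate(self):
        """A shared edge swells at c=0.5 of the free-edge strain, so with
        A=0.4 the closest-vs-farthest edge difference approaches 0.2."""
        cfg = RunConfig(swelling=SwellingConfig(amplitude={"S1": 0.4}))
        state, d = self.make_state(constrained=("right",))
        state.domains = [d]
        add_swelling_signal(state, "S1", cfg)
        advance_time(state, 600.0, cfg)  # effectively equilibrium
        e = domain_edge_lengths(d, state, cfg)
        far = (e["left"] - 200.0) / 200.0
        near = (e["right"] - 200.0) / 200.0
        assert far == pytest.approx(0.4, abs=1e-6)
        assert far - near == pytest.approx(0.2, abs=1e-6)

    def test_negative_time_step_rejected(self):
        state, _ = self.make_state()
        with pytest.raises(InvalidParameterError):
            advance_time(state, -1.0, RunConfig())
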