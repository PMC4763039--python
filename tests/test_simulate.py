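"""Forward simulator: digestion rules, determinism, truth recovery."""

import numpy as np
import pytest

from msapkit.bisulfite import call_methylation, methylation_percentage
from msapkit.core import LanePresence
from msapkit.scoring import BandType, summarize_sample
from msapkit.simulate import (
    STATE_ORDER,
    BisulfiteSimConfig,
    MethylationState,
    SimulationConfig,
    digestion_pattern,
    simulate_bisulfite,
    simulate_msap,
)

STATE_TO_TYPE = {
    MethylationState.U: BandType.I,
    MethylationState.HM_EXT: BandType.II,
    MethylationState.FM_INT: BandType.III,
    MethylationState.X: BandType.IV,
}


def msap_config(**kwargs) -> SimulationConfig:
    defaults = dict(
        n_loci=100,
        samples=["A", "B"],
        state_probs={
            "A": [0.6, 0.1, 0.0, 0.15, 0.15],
            "B": [0.75, 0.05, 0.0, 0.1, 0.1],
        },
        band_noise=0.0,
        seed=11,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestDigestion:
    @pytest.mark.parametrize(
        "state, hpa, msp",
        [
            (MethylationState.U, 1, 1),
            (MethylationState.HM_EXT, 1, 0),
            (MethylationState.HM_INT, 1, 1),
            (MethylationState.FM_INT, 0, 1),
            (MethylationState.X, 0, 0),
        ],
    )
    def test_isoschizomer_sensitivity_rules(self, state, hpa, msp):
        assert digestion_pattern(state) == LanePresence(hpa, msp)

    def test_hemi_internal_is_indistinguishable_from_unmethylated(self):
        # documented MSAP blind spot: both enzymes cut HM_int sites
        assert digestion_pattern(MethylationState.HM_INT) == digestion_pattern(
            MethylationState.U
        )


class TestSimulateMsap:
    def test_degenerate_unmethylated_config_scores_zero(self):
        cfg = msap_config(
            state_probs={"A": [1, 0, 0, 0, 0], "B": [1, 0, 0, 0, 0]}
        )
        matrix, _ = simulate_msap(cfg)
        assert all(p == LanePresence(1, 1) for p in matrix.cells.values())
        assert summarize_sample(matrix, "A").pct_total_methylation == 0.0

    def test_same_seed_reproduces_matrix_and_truth(self):
        m1, t1 = simulate_msap(msap_config())
        m2, t2 = simulate_msap(msap_config())
        assert m1.cells == m2.cells and t1.states == t2.states

    def test_adding_a_sample_preserves_existing_draws(self):
        base = msap_config()
        extended = msap_config(
            samples=["A", "B", "C"],
            state_probs={**base.state_probs, "C": [0.2, 0.2, 0.2, 0.2, 0.2]},
        )
        m1, _ = simulate_msap(base)
        m2, _ = simulate_msap(extended)
        for key, presence in m1.cells.items():
            assert m2.cells[key] == presence

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_msap(msap_config(state_probs={"A": [0.9, 0, 0, 0, 0],
                                                   "B": [1, 0, 0, 0, 0]}))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            simulate_msap(msap_config(band_noise=1.5))

    def test_noise_free_scoring_recovers_truth_exactly(self):
        """With no scoring noise and HM_int disabled, the scorer's type
        counts equal the simulator's state counts under U/HM_ext/FM_int/X
        -> I/II/III/IV."""
        cfg = msap_config(n_loci=2000, seed=3)
        matrix, truth = simulate_msap(cfg)
        for sample in cfg.samples:
            states = truth.state_counts(sample)
            summary = summarize_sample(matrix, sample)
            for state, band_type in STATE_TO_TYPE.items():
                expected = states[state]
                if state is MethylationState.X:
                    # X loci unobserved in every sample are excluded
                    expected = sum(
                        1
                        for locus in matrix.loci
                        if truth.states[(locus, sample)] is MethylationState.X
                        and matrix.observed_elsewhere(locus, sample)
                    )
                assert summary.count(band_type) == expected

    def test_band_noise_perturbs_at_expected_rate(self):
        noise = 0.05
        cfg = msap_config(n_loci=4000, band_noise=noise, seed=9)
        noisy, truth = simulate_msap(cfg)
        flips = sum(
            (digestion_pattern(truth.states[key]).hpa != p.hpa)
            + (digestion_pattern(truth.states[key]).msp != p.msp)
            for key, p in noisy.cells.items()
        )
        n_bits = 2 * len(noisy.cells)
        se = np.sqrt(noise * (1 - noise) / n_bits)
        assert abs(flips / n_bits - noise) < 4 * se


class TestSimulateBisulfite:
    def bs_config(self, **kwargs) -> SimulationConfig:
        samples = [f"S{i}" for i in range(8)]
        return SimulationConfig(
            n_loci=1,
            samples=samples,
            state_probs={s: [1, 0, 0, 0, 0] for s in samples},
            seed=21,
            bisulfite=BisulfiteSimConfig(**kwargs),
        )

    def test_full_conversion_no_methylation_reads_zero_percent(self):
        cfg = self.bs_config(
            context_probs={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            conversion_efficiency=1.0,
        )
        reference, clones, _ = simulate_bisulfite(cfg)
        for seqs in clones.values():
            for clone in seqs:
                assert "C" not in clone
                calls = call_methylation(reference, clone)
                countable = [c for c in calls if c.state.value != "ambiguous"]
                if countable:
                    assert methylation_percentage(calls).pct_methylated == 0.0

    def test_truth_covers_exactly_the_classifiable_cytosines(self):
        cfg = self.bs_config()
        reference, _, truth = simulate_bisulfite(cfg)
        from msapkit.bisulfite import CytosineContext, classify_cytosine_contexts

        classifiable = {
            i
            for i, c in classify_cytosine_contexts(reference)
            if c is not CytosineContext.UNDETERMINED
        }
        for sample in cfg.samples:
            assert {p for (s, p) in truth.flags if s == sample} == classifiable

    def test_same_seed_reproduces_everything(self):
        r1, c1, t1 = simulate_bisulfite(self.bs_config())
        r2, c2, t2 = simulate_bisulfite(self.bs_config())
        assert (r1, c1, t1.flags) == (r2, c2, t2.flags)

    def test_incomplete_conversion_inflates_apparent_methylation(self):
        cfg = self.bs_config(
            context_probs={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            conversion_efficiency=0.6,
            locus_length=600,
        )
        reference, clones, _ = simulate_bisulfite(cfg)
        calls = []
        for seqs in clones.values():
            for clone in seqs:
                calls.extend(call_methylation(reference, clone))
        # residual unconverted Cs read as methylated at rate 1 - efficiency
        pct = methylation_percentage(calls).pct_methylated
        assert 30.0 < pct < 50.0

    def test_injected_context_probabilities_are_recovered(self):
        """Per-context methylation estimates over 200 simulated clones fall
        within 3 binomial standard errors of the injected probabilities."""
        probs = {"CG": 0.8, "CHG": 0.3, "CHH": 0.05}
        samples = [f"S{i}" for i in range(200)]
        cfg = SimulationConfig(
            n_loci=1,
            samples=samples,
            state_probs={s: [1, 0, 0, 0, 0] for s in samples},
            seed=17,
            bisulfite=BisulfiteSimConfig(
                locus_length=400, context_probs=probs, conversion_efficiency=1.0,
                clones_per_sample=1,
            ),
        )
        reference, clones, _ = simulate_bisulfite(cfg)
        calls = []
        for seqs in clones.values():
            for clone in seqs:
                calls.extend(call_methylation(reference, clone))
        summary = methylation_percentage(calls)
        for context, p in probs.items():
            total = summary.n_total[context]
            assert total > 0
            estimate = summary.n_methylated[context] / total
            se = np.sqrt(p * (1 - p) / total)
            assert abs(estimate - p) < 3 * se + 1e-9
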