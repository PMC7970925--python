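"""Synthetic spectrum generation and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from ergolabel.labeling import Hypothesis, TracerSpec, fragment_shift_distribution, propagate
from ergolabel.simulate import (
    SimulationConfig,
    SpectrumPair,
    apparent_shift,
    recovery_experiment,
    simulate_population,
    simulate_spectrum_pair,
    write_spectrum_pair_mgf,
    write_spectrum_pair_tsv,
)


@pytest.fixture(scope="module")
def mep_config(annotations):
    return SimulationConfig(
        hypothesis=Hypothesis("MEP"),
        fragments=tuple(annotations),
        n_molecules=100_000,
        seed=7,
    )


class TestPopulation:
    def test_zero_enrichment_gives_all_false(self, atlas, annotations):
        config = SimulationConfig(
            hypothesis=Hypothesis("MEP"),
            fragments=tuple(annotations),
            tracer=TracerSpec(enrichment=0.0),
            n_molecules=1000,
            seed=1,
        )
        assert not simulate_population(atlas, config).any()

    def test_column_means_match_probabilities(self, atlas, mep_config):
        matrix = simulate_population(atlas, mep_config)
        p = np.array(propagate(atlas, mep_config.tracer, mep_config.hypothesis).p)
        n = mep_config.n_molecules
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(matrix.mean(axis=0) - p) <= 3 * se + 1e-12)

    def test_same_seed_reproduces_matrix(self, atlas, mep_config):
        a = simulate_population(atlas, mep_config)
        b = simulate_population(atlas, mep_config)
        assert (a == b).all()


class TestSpectrumPair:
    def test_unlabeled_pair_is_identical(self, atlas, annotations):
        config = SimulationConfig(
            hypothesis=Hypothesis("MVA"),
            fragments=tuple(annotations),
            tracer=TracerSpec(enrichment=0.0),
            n_molecules=1000,
            detection_threshold=0.0,
            seed=3,
        )
        pair = simulate_spectrum_pair(atlas, config)
        left = pair.neutral.sort_values(["fragment", "mz"]).reset_index(drop=True)
        right = pair.labeled.sort_values(["fragment", "mz"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)

    def test_envelopes_converge_to_analytic_distribution(self, atlas, annotations):
        # Kolmogorov distance between the empirical (noise-free) envelope and
        # the Poisson-binomial prediction, at n = 1e5
        config = SimulationConfig(
            hypothesis=Hypothesis("MEP"),
            fragments=tuple(annotations),
            n_molecules=100_000,
            noise_cv=0.0,
            detection_threshold=0.0,
            seed=11,
        )
        matrix = simulate_population(atlas, config)
        pe = propagate(atlas, config.tracer, config.hypothesis)
        for ann in annotations:
            idx = [c - 1 for c in sorted(ann.carbons)]
            counts = matrix[:, idx].sum(axis=1)
            empirical = np.bincount(counts, minlength=len(idx) + 1) / len(counts)
            analytic = fragment_shift_distribution(ann.carbons, pe).as_array()
            kolmogorov = np.abs(np.cumsum(empirical) - np.cumsum(analytic)).max()
            assert kolmogorov < 0.01

    def test_high_threshold_keeps_at_most_one_peak_per_fragment(self, atlas, annotations):
        config = SimulationConfig(
            hypothesis=Hypothesis("MEP"),
            fragments=tuple(annotations),
            n_molecules=10_000,
            detection_threshold=0.99,
            seed=5,
        )
        pair = simulate_spectrum_pair(atlas, config)
        assert pair.labeled.groupby("fragment").size().max() == 1

    def test_output_formats_roundtrip(self, atlas, mep_config, tmp_path):
        from pyteomics import mgf

        pair = simulate_spectrum_pair(atlas, mep_config)
        paths = write_spectrum_pair_tsv(pair, tmp_path, stem="s")
        assert all(p.exists() for p in paths)
        body = pd.read_csv(paths[1], sep="\t", comment="#")
        assert set(body.columns) == {"fragment", "mz", "intensity"}
        mgf_path = write_spectrum_pair_mgf(pair, tmp_path / "s.mgf")
        spectra = list(mgf.read(str(mgf_path)))
        assert len(spectra) == 2
        assert "seed=7" in spectra[0]["params"]["title"]


class TestApparentShift:
    def _pair(self, intensities, shifts, mz0=100):
        labeled = pd.DataFrame(
            {"fragment": f"{mz0}:1-2", "mz": [mz0 + s for s in shifts], "intensity": intensities}
        )
        neutral = pd.DataFrame({"fragment": [f"{mz0}:1-2"], "mz": [mz0], "intensity": [1.0]})
        return SpectrumPair(neutral=neutral, labeled=labeled, metadata={"condition": "t"})

    class _Frag:
        nominal_mz = 100
        carbons = frozenset({1, 2})

    def test_reading_rules(self):
        pair = self._pair([0.2, 0.7, 0.1], [0, 1, 2])
        assert apparent_shift(pair, self._Frag(), rule="max-intensity").shift == 1
        assert apparent_shift(pair, self._Frag(), rule="max-mz").shift == 2

    def test_unlabeled_pair_reads_zero_under_both_rules(self):
        pair = self._pair([1.0], [0])
        for rule in ("max-intensity", "max-mz"):
            assert apparent_shift(pair, self._Frag(), rule=rule).shift == 0

    def test_single_peak_rules_agree(self):
        pair = self._pair([1.0], [3])
        assert apparent_shift(pair, self._Frag(), rule="max-intensity").shift == 3
        assert apparent_shift(pair, self._Frag(), rule="max-mz").shift == 3

    def test_intensity_tie_breaks_toward_larger_shift(self):
        pair = self._pair([0.5, 0.5], [1, 2])
        assert apparent_shift(pair, self._Frag(), rule="max-intensity").shift == 2

    def test_absent_fragment_raises(self):
        pair = self._pair([1.0], [0])

        class Other:
            nominal_mz = 999
            carbons = frozenset({3})

        with pytest.raises(LookupError):
            apparent_shift(pair, Other())


@pytest.fixture(scope="module")
def table(atlas, annotations):
    return recovery_experiment(
        atlas,
        hypotheses=(Hypothesis("MVA"), Hypothesis("MEP")),
        enrichments=(0.2, 0.985),
        fragments=annotations,
        seed=1,
    )


class TestRecovery:
    def test_mep_majority_recovered_at_full_enrichment(self, table):
        cell = table[(table.hypothesis == "MEP") & (table.enrichment == 0.985)]
        assert cell.fraction_correct.iloc[0] > 0.5

    def test_recovery_is_monotone_in_enrichment(self, table):
        for hyp in ("MVA", "MEP"):
            sub = table[table.hypothesis == hyp].sort_values("enrichment")
            fractions = sub.fraction_correct.to_numpy()
            assert np.all(np.diff(fractions) >= 0)

    def test_frozen_regression_values(self, table):
        # first-run reference under the default study conditions, seed 1
        got = {
            (r.hypothesis, r.enrichment): r.fraction_correct for r in table.itertuples()
        }
        assert got[("MEP", 0.985)] == pytest.approx(0.8)
        assert got[("MEP", 0.2)] == pytest.approx(0.2)
        assert got[("MVA", 0.985)] == pytest.approx(0.6)
        assert got[("MVA", 0.2)] == pytest.approx(0.0)

    def test_same_seed_reproduces_table(self, atlas, annotations, table):
        again = recovery_experiment(
            atlas,
            hypotheses=(Hypothesis("MVA"), Hypothesis("MEP")),
            enrichments=(0.2, 0.985),
            fragments=annotations,
            seed=1,
        )
        pd.testing.assert_frame_equal(table, again)

    def test_zero_enrichment_recovers_nothing(self, atlas, annotations):
        table = recovery_experiment(
            atlas,
            hypotheses=(Hypothesis("MEP"),),
            enrichments=(0.0,),
            fragments=annotations,
            n_molecules=2000,
            seed=2,
        )
        assert table.n_correct.iloc[0] == 0

    def test_mixture_grid_rejected(self, atlas, annotations):
        with pytest.raises(ValueError):
            recovery_experiment(
                atlas,
                hypotheses=(Hypothesis("mixture", alpha=0.5),),
                enrichments=(0.985,),
                fragments=annotations,
                seed=1,
            )
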