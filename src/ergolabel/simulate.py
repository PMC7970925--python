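"""Synthetic product-ion spectrum pairs for parameter-recovery experiments.

Emulates the labeled-culture experiment: a population of product molecules
assembles with independent per-position Bernoulli heavy labels drawn from
the propagated tracer enrichment; each fragment's labeled envelope is the
empirical histogram of heavy-label counts over its retained carbons, under
multiplicative lognormal intensity noise and a relative detection
threshold.  No chromatography, adducts beyond the dehydrated protonated
parent, or profile-mode peaks are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .atlas import Atlas
from .classify import ShiftObservation, classify
from .fragments import FragmentAnnotation, FragmentCandidate, format_carbon_set
from .labeling import Hypothesis, TracerSpec, propagate

__all__ = [
    "SimulationConfig",
    "SpectrumPair",
    "simulate_population",
    "simulate_spectrum_pair",
    "apparent_shift",
    "recovery_experiment",
    "write_spectrum_pair_tsv",
    "write_spectrum_pair_mgf",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic spectrum pair.

    Defaults emulate the labeled culture: [1-13C]glucose at 98.5% isotopic
    enrichment, 1e5 product molecules, 10% multiplicative intensity noise
    (a standard MS intensity error magnitude) and a 5% relative detection
    threshold standing in for the instrument limit that truncates weak
    high-shift isotopologues.
    """

    hypothesis: Hypothesis
    fragments: tuple
    tracer: TracerSpec = TracerSpec()
    molecule: str = "ergosterol"
    n_molecules: int = 100_000
    noise_cv: float = 0.1
    detection_threshold: float = 0.05
    natural_abundance: bool = False
    condition: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 0.0 <= self.detection_threshold < 1.0:
            raise ValueError("detection_threshold must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not self.fragments:
            raise ValueError("fragment set must be nonempty")


@dataclass(frozen=True)
class SpectrumPair:
    """Neutral and labeled peak lists (columns fragment, mz, intensity;
    intensities normalized to max = 1 within each fragment's envelope)."""

    neutral: pd.DataFrame
    labeled: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _fragment_key(frag) -> tuple[int, frozenset[int]]:
    return int(frag.nominal_mz), frozenset(frag.carbons)


def simulate_population(atlas: Atlas, config: SimulationConfig) -> np.ndarray:
    """Draw the per-molecule boolean label matrix (n_molecules x n_carbons).

    Column ``i`` is Bernoulli with the propagated probability of carbon
    ``i+1``; reproducible for a fixed seed.
    """
    pe = propagate(atlas, config.tracer, config.hypothesis, config.molecule)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    p = np.asarray(pe.p)
    return rng.random((config.n_molecules, p.size)) < p


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_spectrum_pair(atlas: Atlas, config: SimulationConfig) -> SpectrumPair:
    """Simulate the neutral/labeled product-ion spectrum pair.

    The labeled envelope of each fragment is the empirical shift histogram
    of summed labels over its carbons across the population, times lognormal
    noise, renormalized to max = 1 and thresholded; it is placed at
    ``neutral_mz + shift``.  The neutral spectrum carries the same fragments
    at shift 0 (with natural-abundance satellites when enabled).
    """
    matrix = simulate_population(atlas, config)
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pe = propagate(atlas, config.tracer, config.hypothesis, config.molecule)

    neutral_rows, labeled_rows = [], []
    for frag in config.fragments:
        mz0, carbons = _fragment_key(frag)
        idx = [c - 1 for c in sorted(carbons)]
        counts = matrix[:, idx].sum(axis=1)
        envelope = np.bincount(counts, minlength=len(idx) + 1).astype(float)
        envelope /= envelope.max()
        envelope *= _lognormal_factors(noise_rng, config.noise_cv, envelope.size)
        envelope /= envelope.max()
        name = f"{mz0}:{format_carbon_set(carbons)}"
        for shift, intensity in enumerate(envelope):
            if intensity > 0 and intensity >= config.detection_threshold:
                labeled_rows.append(
                    {"fragment": name, "mz": mz0 + shift, "intensity": float(intensity)}
                )
        if config.natural_abundance:
            from .labeling import PositionEnrichment, fragment_shift_distribution

            blank = PositionEnrichment(config.molecule, (0.0,) * len(pe))
            na = fragment_shift_distribution(carbons, blank, natural_abundance=True)
            sat = np.asarray(na.shifts) / max(na.shifts)
            for shift, intensity in enumerate(sat):
                if intensity >= config.detection_threshold and intensity > 0:
                    neutral_rows.append(
                        {"fragment": name, "mz": mz0 + shift, "intensity": float(intensity)}
                    )
        else:
            neutral_rows.append({"fragment": name, "mz": mz0, "intensity": 1.0})

    metadata = {
        "seed": config.seed,
        "hypothesis": config.hypothesis.route,
        "alpha": config.hypothesis.alpha,
        "enrichment": config.tracer.enrichment,
        "n_molecules": config.n_molecules,
        "noise_cv": config.noise_cv,
        "detection_threshold": config.detection_threshold,
        "condition": config.condition,
    }
    return SpectrumPair(
        neutral=pd.DataFrame(neutral_rows),
        labeled=pd.DataFrame(labeled_rows),
        metadata=metadata,
    )


def apparent_shift(pair: SpectrumPair, fragment, rule: str = "max-mz") -> ShiftObservation:
    """Read a single mass shift off a fragment's labeled envelope.

    ``max-intensity`` returns the most intense surviving isotopologue's
    shift; ``max-mz`` the largest surviving shift (how a labeled parent ion
    read as the "maximum" observed m/z is obtained).  Ties break toward the
    larger shift.
    """
    mz0, carbons = _fragment_key(fragment)
    name = f"{mz0}:{format_carbon_set(carbons)}"
    peaks = pair.labeled[pair.labeled["fragment"] == name]
    if peaks.empty:
        raise LookupError(f"fragment {name} absent from labeled spectrum")
    shifts = peaks["mz"].to_numpy() - mz0
    if rule == "max-mz":
        shift = int(shifts.max())
    elif rule == "max-intensity":
        intensities = peaks["intensity"].to_numpy()
        best = intensities.max()
        shift = int(shifts[np.isclose(intensities, best)].max())
    else:
        raise ValueError(f"unknown reading rule: {rule!r}")
    return ShiftObservation(
        neutral_mz=mz0,
        labeled_mz=mz0 + shift,
        condition=pair.metadata.get("condition", ""),
    )


def recovery_experiment(
    atlas: Atlas,
    hypotheses,
    enrichments,
    fragments,
    repetitions: int = 1,
    seed: int = 0,
    n_molecules: int = 100_000,
    noise_cv: float = 0.1,
    detection_threshold: float = 0.05,
    rule: str = "max-mz",
    molecule: str = "ergosterol",
) -> pd.DataFrame:
    """Simulate-then-classify over a (hypothesis x enrichment) grid.

    For each cell and repetition: simulate a spectrum pair, read each
    fragment's apparent shift, classify it, and report the fraction of
    pathway-discriminating fragments (different predicted counts under the
    two hypotheses) whose verdict equals the generating route.  Reproducible
    given ``seed``.
    """
    base = TracerSpec()
    annotations = [
        f if isinstance(f, FragmentAnnotation)
        else FragmentAnnotation(nominal_mz=f.nominal_mz, carbons=f.carbons)
        for f in fragments
    ]
    rows = []
    cell = 0
    for hyp in hypotheses:
        if hyp.is_mixture:
            raise ValueError("recovery grid requires pure hypotheses")
        for e in enrichments:
            tracer = replace(base, enrichment=e)
            from .labeling import labelable_positions, propagate as _prop

            lab = {
                r: labelable_positions(_prop(atlas, tracer, Hypothesis(r), molecule))
                for r in ("MVA", "MEP")
            }
            for rep in range(repetitions):
                config = SimulationConfig(
                    hypothesis=hyp,
                    fragments=tuple(fragments),
                    tracer=tracer,
                    molecule=molecule,
                    n_molecules=n_molecules,
                    noise_cv=noise_cv,
                    detection_threshold=detection_threshold,
                    condition=f"{hyp.route}:e={e}",
                    seed=int(np.random.SeedSequence([seed, cell]).generate_state(1)[0] % 2**31),
                )
                cell += 1
                pair = simulate_spectrum_pair(atlas, config)
                n_disc = n_correct = 0
                for frag in fragments:
                    _, carbons = _fragment_key(frag)
                    if len(lab["MVA"] & carbons) == len(lab["MEP"] & carbons):
                        continue  # fragment cannot discriminate the routes
                    n_disc += 1
                    obs = apparent_shift(pair, frag, rule=rule)
                    rec = classify(
                        atlas, obs, annotations=annotations, mode="annotated",
                        tracer=tracer, molecule=molecule,
                    )
                    if rec.verdict == hyp.route:
                        n_correct += 1
                rows.append(
                    {
                        "hypothesis": hyp.route,
                        "enrichment": e,
                        "repetition": rep,
                        "n_fragments": len(fragments),
                        "n_discriminating": n_disc,
                        "n_correct": n_correct,
                        "fraction_correct": n_correct / n_disc if n_disc else np.nan,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output formats


def write_spectrum_pair_tsv(pair: SpectrumPair, directory, stem: str = "spectrum") -> list[Path]:
    """Write the pair as two TSV peak lists with a metadata header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    header = "".join(f"# {k}={v}\n" for k, v in sorted(pair.metadata.items()))
    for label, df in (("neutral", pair.neutral), ("labeled", pair.labeled)):
        path = directory / f"{stem}_{label}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
        paths.append(path)
    return paths


def write_spectrum_pair_mgf(pair: SpectrumPair, path) -> Path:
    """Write the pair as MGF, one BEGIN/END IONS block per spectrum, TITLE
    carrying the condition and seed."""
    spectra = []
    for label, df in (("neutral", pair.neutral), ("labeled", pair.labeled)):
        df = df.sort_values("mz")
        spectra.append(
            {
                "m/z array": df["mz"].to_numpy(dtype=float),
                "intensity array": df["intensity"].to_numpy(dtype=float),
                "params": {
                    "title": (
                        f"{label} condition={pair.metadata.get('condition')} "
                        f"seed={pair.metadata.get('seed')}"
                    ),
                    "charge": "1+",
                },
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")
    return Path(path)
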