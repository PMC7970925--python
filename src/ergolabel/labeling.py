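"""Tracer propagation and fragment isotopologue-shift distributions.

Given a tracer (which glucose carbons carry the heavy isotope, at what
isotopic enrichment) and a pathway hypothesis (MVA, MEP, or a flux mixture),
this module computes the per-carbon probability that each position of a
route product is heavy, and from those probabilities the integer mass-shift
distribution of any carbon subset (a product-ion fragment) as a
Poisson-binomial of independent per-position Bernoulli labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas, CarbonOrigin, trace_origin

__all__ = [
    "TracerSpec",
    "Hypothesis",
    "MVA",
    "MEP",
    "PositionEnrichment",
    "IsotopologueDistribution",
    "propagate",
    "labelable_positions",
    "fragment_shift_distribution",
    "predicted_count",
    "write_enrichment_report",
]

#: default per-position natural abundance of the heavy carbon isotope
NATURAL_ABUNDANCE_13C = 0.0107


@dataclass(frozen=True)
class TracerSpec:
    """A position-labeled substrate.

    Default: glucose labeled at C1 with isotopic enrichment 0.985 (the
    midpoint of the 98-99% purity range of commercial [1-13C]glucose).
    ``sam_enrichment`` optionally assigns a label probability to the SAM
    methyl pool for sensitivity analysis (one-carbon metabolism is not
    modeled; default unlabeled).
    """

    substrate: str = "glucose"
    labeled_positions: frozenset[int] = frozenset({1})
    enrichment: float = 0.985
    sam_enrichment: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError(f"enrichment must be in [0, 1], got {self.enrichment}")
        if not 0.0 <= self.sam_enrichment <= 1.0:
            raise ValueError("sam_enrichment must be in [0, 1]")


@dataclass(frozen=True)
class Hypothesis:
    """A pathway-of-origin hypothesis: a pure route or a flux mixture.

    ``alpha`` is the fraction of flux through the MEP route and is defined
    only for mixtures.
    """

    route: str  # "MVA", "MEP", or "mixture"
    alpha: float | None = None

    def __post_init__(self):
        if self.route == "mixture":
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValueError("mixture hypothesis needs alpha in [0, 1]")
        elif self.alpha is not None:
            raise ValueError("alpha is defined only for mixture hypotheses")

    @property
    def is_mixture(self) -> bool:
        return self.route == "mixture"


MVA = Hypothesis("MVA")
MEP = Hypothesis("MEP")


@dataclass(frozen=True)
class PositionEnrichment:
    """Per-carbon heavy-isotope probabilities, index-aligned with the
    molecule's canonical numbering (``p[0]`` is C1)."""

    molecule: str
    p: tuple[float, ...]

    def __post_init__(self):
        if any(not 0.0 <= x <= 1.0 for x in self.p):
            raise ValueError("position probabilities must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.p)

    def probability(self, carbon: int) -> float:
        return self.p[carbon - 1]


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Probabilities q_0..q_n over integer mass shifts of a fragment."""

    shifts: tuple[float, ...]

    def __post_init__(self):
        total = sum(self.shifts)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"shift distribution must sum to 1, got {total!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.shifts)

    @property
    def expected_shift(self) -> float:
        return float(sum(k * q for k, q in enumerate(self.shifts)))


def _position_probabilities(origin: CarbonOrigin, tracer: TracerSpec) -> np.ndarray:
    n = len(origin.glucose_fractions)
    p = np.zeros(n)
    for c in range(1, n + 1):
        mass = sum(
            frac
            for glc_carbon, frac in origin.glucose_fractions[c].items()
            if glc_carbon in tracer.labeled_positions
        )
        p[c - 1] = mass * tracer.enrichment + origin.sam_fraction[c] * tracer.sam_enrichment
    return p


def propagate(
    atlas: Atlas,
    tracer: TracerSpec,
    hypothesis: Hypothesis,
    molecule: str = "ergosterol",
) -> PositionEnrichment:
    """Per-carbon heavy-label probabilities of ``molecule`` under a hypothesis.

    For a pure route, ``p_i`` sums branch probability x enrichment over every
    backward branch ending at a labeled glucose carbon.  For a mixture,
    ``p = alpha * p_MEP + (1 - alpha) * p_MVA`` position-wise (each molecule
    is made entirely by one route, drawn with probability alpha).
    """
    if hypothesis.is_mixture:
        p_mep = _position_probabilities(trace_origin(atlas, molecule, "MEP"), tracer)
        p_mva = _position_probabilities(trace_origin(atlas, molecule, "MVA"), tracer)
        p = hypothesis.alpha * p_mep + (1.0 - hypothesis.alpha) * p_mva
    else:
        p = _position_probabilities(trace_origin(atlas, molecule, hypothesis.route), tracer)
    return PositionEnrichment(molecule=molecule, p=tuple(float(x) for x in p))


def labelable_positions(pe: PositionEnrichment, eps: float = 1e-9) -> frozenset[int]:
    """Carbons with label probability above ``eps`` (floating-point hygiene
    only — theoretically labelable means strictly positive probability)."""
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    return frozenset(c for c in range(1, len(pe) + 1) if pe.probability(c) > eps)


def fragment_shift_distribution(
    subset,
    pe: PositionEnrichment,
    natural_abundance: bool = False,
    a13: float = NATURAL_ABUNDANCE_13C,
) -> IsotopologueDistribution:
    """Poisson-binomial mass-shift distribution of a fragment.

    Each retained position contributes an independent Bernoulli with its
    tracer-derived probability; with ``natural_abundance`` on, the unlabeled
    channel of every position additionally carries the background heavy
    fraction, ``q_i = p_i + (1 - p_i) * a13``.  Computed by iterative
    convolution (exact, O(n^2)).
    """
    if pe is None or len(pe) == 0:
        raise ValueError("empty position enrichment")
    subset = sorted(set(subset))
    if any(not 1 <= c <= len(pe) for c in subset):
        raise ValueError(f"fragment carbons out of range for {pe.molecule}")
    q = np.array([1.0])
    for c in subset:
        pi = pe.probability(c)
        if natural_abundance:
            pi = pi + (1.0 - pi) * a13
        q = np.convolve(q, [1.0 - pi, pi])
    q = q / q.sum()  # guard rounding drift; exact sums stay untouched
    return IsotopologueDistribution(shifts=tuple(float(x) for x in q))


def predicted_count(
    atlas: Atlas,
    subset,
    hypothesis: Hypothesis,
    tracer: TracerSpec | None = None,
    molecule: str = "ergosterol",
    eps: float = 1e-9,
) -> int:
    """Number of theoretically labelable positions a fragment retains.

    This is the predicted full-incorporation mass shift of the fragment
    under a pure pathway hypothesis; mixtures have no single predicted count
    and are rejected.
    """
    if hypothesis.is_mixture:
        raise ValueError("predicted counts are undefined for mixture hypotheses")
    tracer = tracer or TracerSpec()
    pe = propagate(atlas, tracer, hypothesis, molecule)
    return len(labelable_positions(pe, eps) & set(subset))


def write_enrichment_report(
    atlas: Atlas,
    tracer: TracerSpec,
    molecules,
    path=None,
) -> pd.DataFrame:
    """Per-molecule table of carbon origin and per-route label probabilities
    (columns: molecule, carbon, origin, p_MVA, p_MEP); written as TSV when
    ``path`` is given."""
    from .atlas import RouteError

    rows = []
    for mol in molecules:
        origins, p = {}, {}
        for r in ("MVA", "MEP"):
            try:
                origins[r] = trace_origin(atlas, mol, r)
                p[r] = _position_probabilities(origins[r], tracer)
            except RouteError:
                pass  # route-specific intermediate; report the reachable route only
        if not origins:
            raise RouteError(f"molecule {mol!r} unreachable on both routes")
        any_origin = next(iter(origins.values()))
        n = atlas.molecule(mol).n_carbons
        for c in range(1, n + 1):
            rows.append(
                {
                    "molecule": mol,
                    "carbon": c,
                    "origin": any_origin.origin_class(c),
                    "p_MVA": round(float(p["MVA"][c - 1]), 9) if "MVA" in p else np.nan,
                    "p_MEP": round(float(p["MEP"][c - 1]), 9) if "MEP" in p else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
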