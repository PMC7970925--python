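"""Candidate fragment structures for nominal product-ion masses.

A product-ion fragment is modeled as a connected carbon subset of the parent
sterol skeleton plus a hydrogen count; oxygen is assumed lost with the
initial water loss of the [M+H-H2O]+ parent, so all fragment ions are
hydrocarbon cations at nominal (unit) resolution.  Fragment structures can
either be enumerated combinatorially (bounded bond-cleavage search over the
skeleton graph) or ingested from an annotation table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import networkx as nx
import pandas as pd

from .atlas import MoleculeSpec, parse_formula

__all__ = [
    "FragmentCandidate",
    "FragmentAnnotation",
    "FragmentError",
    "nominal_mass",
    "candidate_formulas",
    "enumerate_fragments",
    "rank_candidates",
    "read_annotations",
    "parse_carbon_set",
    "format_carbon_set",
]

_NOMINAL = {"C": 12, "H": 1, "O": 16}

#: hydride shifts and H2 losses dominate sterol fragmentation; allow the
#: fragment hydrogen count to deviate from the retained skeleton hydrogens
#: by at most this much
HYDROGEN_SLACK = 2


class FragmentError(ValueError):
    """Invalid fragment definition (disconnected set, bad carbon index...)."""


@dataclass(frozen=True)
class FragmentCandidate:
    """A connected carbon subset of the parent with an assigned formula."""

    parent: str
    carbons: frozenset[int]
    hydrogens: int
    formula: str
    nominal_mz: int
    n_cleavages: int
    charge: int = 1
    rank: int | None = None

    def with_rank(self, rank: int) -> "FragmentCandidate":
        return FragmentCandidate(
            self.parent, self.carbons, self.hydrogens, self.formula,
            self.nominal_mz, self.n_cleavages, self.charge, rank,
        )


@dataclass(frozen=True)
class FragmentAnnotation:
    """An externally assigned fragment structure for one nominal m/z."""

    nominal_mz: int
    carbons: frozenset[int]
    source: str = ""


def nominal_mass(formula: str | dict[str, int], charge: int = 1) -> int:
    """Integer nominal mass (C=12, H=1, O=16) of a CHO composition.

    For cations this is the mass of the ion's atoms; the electron mass is
    invisible at unit resolution.
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    unsupported = set(counts) - set(_NOMINAL)
    if unsupported:
        raise FragmentError(f"unsupported elements for nominal mass: {sorted(unsupported)}")
    return sum(_NOMINAL[el] * n for el, n in counts.items())


def _format_formula(c: int, h: int, o: int) -> str:
    out = f"C{c}H{h}" if c != 1 else f"CH{h}"
    if o == 1:
        out += "O"
    elif o > 1:
        out += f"O{o}"
    return out


def _dbe(c: int, h: int) -> float:
    # ring-plus-double-bond equivalents; half-integral for even-electron cations
    return (2 * c + 2 - h) / 2


def candidate_formulas(
    nominal_mz: int,
    max_c: int = 28,
    max_o: int = 1,
    dbe_range: tuple[float, float] = (0.5, 14.5),
) -> list[tuple[str, int, int, int]]:
    """All CxHy(Oz) compositions with the requested nominal mass.

    Constraints: C <= ``max_c``, O <= ``max_o``, H <= 2C+2, and cation DBE
    within ``dbe_range``.  Sorted by fewest heteroatoms, then highest DBE
    (condensed ring fragments before open-chain rearrangement products),
    then carbon count.  Returns ``(formula, C, H, O)`` tuples; an impossible
    mass yields an empty list.
    """
    out = []
    for o in range(0, max_o + 1):
        for c in range(1, max_c + 1):
            h = nominal_mz - 12 * c - 16 * o
            if h < 0 or h > 2 * c + 2:
                continue
            dbe = _dbe(c, h)
            if not dbe_range[0] <= dbe <= dbe_range[1]:
                continue
            out.append((_format_formula(c, h, o), c, h, o))
    out.sort(key=lambda t: (t[3], -_dbe(t[1], t[2]), t[1]))
    return out


def _skeleton_graph(parent: MoleculeSpec) -> nx.Graph:
    if parent.skeleton_bonds is None:
        raise FragmentError(f"molecule {parent.id!r} has no skeleton bonds")
    g = nx.Graph()
    g.add_nodes_from(range(1, parent.n_carbons + 1))
    g.add_edges_from(parent.skeleton_bonds)
    return g


def _boundary_size(g: nx.Graph, subset: frozenset[int]) -> int:
    return sum(1 for u, v in g.edges if (u in subset) != (v in subset))


def connected_subsets_by_cleavage(g: nx.Graph, max_cleavages: int):
    """Connected node subsets separable by breaking <= ``max_cleavages`` edges.

    Yields ``(subset, n_cleavages)`` where ``n_cleavages`` is the exact
    boundary size.  Enumerated by deleting every edge combination up to the
    budget and collecting components whose boundary lies inside the deleted
    set — complete, because a subset with boundary size b <= k is a component
    after deleting exactly its b boundary edges.
    """
    edges = list(g.edges)
    seen: dict[frozenset[int], int] = {}
    for k in range(0, max_cleavages + 1):
        for cut in itertools.combinations(edges, k):
            h = g.copy()
            h.remove_edges_from(cut)
            for comp in nx.connected_components(h):
                subset = frozenset(comp)
                if subset in seen:
                    continue
                b = _boundary_size(g, subset)
                if b <= max_cleavages:
                    seen[subset] = b
    yield from seen.items()


@lru_cache(maxsize=256)
@lru_cache(maxsize=32)
def _cleavage_subsets(parent: MoleculeSpec, max_cleavages: int) -> tuple:
    return tuple(connected_subsets_by_cleavage(_skeleton_graph(parent), max_cleavages))


def enumerate_fragments(
    parent: MoleculeSpec,
    target_mz: int,
    max_cleavages: int = 3,
    hydrogen_slack: int = HYDROGEN_SLACK,
) -> list[FragmentCandidate]:
    """Enumerate fragment structures explaining a nominal product-ion mass.

    A candidate is a connected carbon subset separable from the parent
    skeleton by at most ``max_cleavages`` bond breaks, whose carbon count has
    a hydrocarbon formula at ``target_mz`` reachable within the hydrogen
    rearrangement slack (retained skeleton hydrogens +/- ``hydrogen_slack``).
    Candidates are deduplicated by carbon set and returned ranked (see
    :func:`rank_candidates`).
    """
    if parent.carbon_hydrogens is None:
        raise FragmentError(f"molecule {parent.id!r} has no per-carbon hydrogen counts")
    formulas = {
        c: (formula, h)
        for formula, c, h, o in candidate_formulas(target_mz, max_c=parent.n_carbons)
        if o == 0
    }
    if not formulas:
        return []
    candidates = []
    for subset, n_cuts in _cleavage_subsets(parent, max_cleavages):
        hit = formulas.get(len(subset))
        if hit is None:
            continue
        formula, h = hit
        retained_h = sum(parent.carbon_hydrogens[c - 1] for c in subset)
        if abs(h - retained_h) > hydrogen_slack:
            continue
        candidates.append(
            FragmentCandidate(
                parent=parent.id,
                carbons=subset,
                hydrogens=h,
                formula=formula,
                nominal_mz=target_mz,
                n_cleavages=n_cuts,
            )
        )
    return rank_candidates(candidates, parent)


def rank_candidates(
    candidates: list[FragmentCandidate],
    parent: MoleculeSpec | None = None,
) -> list[FragmentCandidate]:
    """Deterministic total order: fewest cleavages first, side-chain-terminus
    containing candidates preferred within a tie, then lexicographic carbon
    set.  Rank fields are assigned 1..k."""
    terminus = parent.side_chain_terminus if parent is not None else None

    def key(c: FragmentCandidate):
        has_terminus = 0 if (terminus is not None and terminus in c.carbons) else 1
        return (c.n_cleavages, has_terminus, tuple(sorted(c.carbons)))

    ordered = sorted(candidates, key=key)
    return [c.with_rank(i + 1) for i, c in enumerate(ordered)]


# ---------------------------------------------------------------------------
# annotation ingestion


def parse_carbon_set(spec: str) -> frozenset[int]:
    """Parse a comma/range carbon list like ``"1-4,10,19"``."""
    out: set[int] = set()
    for token in str(spec).split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            lo, hi = token.split("-", 1)
            lo, hi = int(lo), int(hi)
            if hi < lo:
                raise FragmentError(f"bad carbon range: {token!r}")
            out.update(range(lo, hi + 1))
        else:
            out.add(int(token))
    if not out:
        raise FragmentError(f"empty carbon set: {spec!r}")
    return frozenset(out)


def format_carbon_set(carbons) -> str:
    """Inverse of :func:`parse_carbon_set` (compact range notation)."""
    items = sorted(carbons)
    runs = []
    start = prev = items[0]
    for c in items[1:] + [None]:
        if c is not None and c == prev + 1:
            prev = c
            continue
        runs.append(str(start) if start == prev else f"{start}-{prev}")
        if c is not None:
            start = prev = c
    return ",".join(runs)


def validate_annotation(ann: FragmentAnnotation, parent: MoleculeSpec) -> None:
    bad = [c for c in ann.carbons if not 1 <= c <= parent.n_carbons]
    if bad:
        raise FragmentError(
            f"annotation for m/z {ann.nominal_mz}: unknown carbon indices {sorted(bad)}"
        )
    g = _skeleton_graph(parent).subgraph(ann.carbons)
    if not nx.is_connected(g):
        raise FragmentError(
            f"annotation for m/z {ann.nominal_mz}: carbon set "
            f"{format_carbon_set(ann.carbons)} is not connected in {parent.id}"
        )


def read_annotations(path: str | Path, parent: MoleculeSpec) -> list[FragmentAnnotation]:
    """Read and validate a fragment-annotation TSV.

    Columns: ``nominal_mz``, ``carbons`` (comma/range list), ``source``.
    Every carbon set must be connected in the parent skeleton.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    required = {"nominal_mz", "carbons"}
    missing = required - set(df.columns)
    if missing:
        raise FragmentError(f"{path}: missing annotation columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        ann = FragmentAnnotation(
            nominal_mz=int(row["nominal_mz"]),
            carbons=parse_carbon_set(row["carbons"]),
            source=str(row.get("source", "")),
        )
        validate_annotation(ann, parent)
        out.append(ann)
    return out


def packaged_annotations_path() -> Path:
    from importlib import resources

    return Path(resources.files("ergolabel.data") / "fragment_annotations_synthetic.tsv")
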