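"""Atom-mapped reaction atlas and carbon-provenance tracing.

The atlas is data, not code: molecules, atom-mapped reactions and routes are
read from a YAML document (see ``data/atlas.yaml`` for the packaged default
covering glucose -> ergosterol via the mevalonate and methylerythritol-
phosphate routes).  This module validates the maps (strict carbon
conservation) and composes them forward to answer, for every carbon of a
target molecule, which glucose carbons it can derive from and with what
branch probability.

Carbon indices are 1-based and per-molecule canonical.  Transitions are
written as ``"pyr.C3 -> dxp.C1"``; merge (pool-mixing) reactions carry branch
weights, ``"a.C1 -> g.C1 @ 0.5"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "MoleculeSpec",
    "Transition",
    "ReactionMap",
    "PathwayRoute",
    "CarbonOrigin",
    "Atlas",
    "AtlasError",
    "AtlasParseError",
    "AtlasValidationError",
    "RouteError",
    "parse_formula",
    "load_atlas",
    "packaged_atlas_path",
    "validate_reaction",
    "trace_origin",
    "unit_positions",
]

SAM_SOURCE = "SAM"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_TRANSITION_RE = re.compile(
    r"^\s*(\w+)\.C(\d+)\s*->\s*(\w+)\.C(\d+)\s*(?:@\s*([0-9.eE+-]+))?\s*$"
)


class AtlasError(Exception):
    """Base class for atlas problems."""


class AtlasParseError(AtlasError):
    """Malformed atlas document (schema violation)."""


class AtlasValidationError(AtlasError):
    """Structurally parseable atlas that violates a carbon-map invariant."""


class RouteError(AtlasError):
    """A route does not compose, or a target is unreachable on it."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition like ``C28H44O`` into counts."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise AtlasParseError(f"malformed formula: {formula!r}")
    counts: dict[str, int] = {}
    for element, n in _FORMULA_RE.findall(formula):
        if element:
            counts[element] = counts.get(element, 0) + (int(n) if n else 1)
    return counts


@dataclass(frozen=True)
class MoleculeSpec:
    """A molecule at carbon-skeleton resolution."""

    id: str
    n_carbons: int
    numbering: str
    formula: str
    skeleton_bonds: tuple[tuple[int, int], ...] | None = None
    carbon_hydrogens: tuple[int, ...] | None = None
    side_chain_terminus: int | None = None

    def validate(self) -> list[str]:
        problems = []
        if self.n_carbons < 1:
            problems.append(f"{self.id}: n_carbons must be positive")
        try:
            counts = parse_formula(self.formula)
        except AtlasParseError as exc:
            return problems + [f"{self.id}: {exc}"]
        if counts.get("C", 0) != self.n_carbons:
            problems.append(
                f"{self.id}: formula carbon count {counts.get('C', 0)} "
                f"!= n_carbons {self.n_carbons}"
            )
        if self.skeleton_bonds is not None:
            for i, j in self.skeleton_bonds:
                if not (1 <= i <= self.n_carbons and 1 <= j <= self.n_carbons):
                    problems.append(f"{self.id}: skeleton bond ({i},{j}) out of range")
                if i == j:
                    problems.append(f"{self.id}: self-bond ({i},{j})")
        if self.carbon_hydrogens is not None and len(self.carbon_hydrogens) != self.n_carbons:
            problems.append(f"{self.id}: carbon_hydrogens length != n_carbons")
        return problems


@dataclass(frozen=True)
class Transition:
    substrate_role: str
    substrate_carbon: int
    product_role: str
    product_carbon: int
    weight: float = 1.0


@dataclass(frozen=True)
class ReactionMap:
    """One biochemical reaction with explicit substrate->product carbon map.

    ``kind`` is ``"transition"`` for ordinary reactions (each product carbon
    has exactly one parent) or ``"merge"`` for pool-mixing steps (each product
    carbon has several weighted parents whose weights sum to 1).
    """

    id: str
    name: str
    substrates: tuple[tuple[str, str], ...]  # (molecule id, role)
    products: tuple[tuple[str, str], ...]
    transitions: tuple[Transition, ...]
    lost_carbons: tuple[tuple[str, int, str], ...] = ()  # (role, carbon, sink)
    gained_carbons: tuple[tuple[str, int, str], ...] = ()  # (role, carbon, source)
    kind: str = "transition"
    unit_roles: dict[str, int] | None = None
    role_unit_offset: dict[str, int] | None = None

    @property
    def substrate_roles(self) -> dict[str, str]:
        return {role: mol for mol, role in self.substrates}

    @property
    def product_roles(self) -> dict[str, str]:
        return {role: mol for mol, role in self.products}


@dataclass(frozen=True)
class PathwayRoute:
    id: str
    reactions: tuple[str, ...]
    inputs: tuple[str, ...] = ("glucose",)


@dataclass(frozen=True)
class CarbonOrigin:
    """Backward carbon provenance of one molecule on one route.

    ``glucose_fractions[c]`` maps glucose carbon index -> branch probability
    (mass not summing to 1 is external, e.g. SAM).  For molecules downstream
    of prenyl assembly, ``units[c]`` is ``(unit 1..6, IPP position 1..5)``;
    for the SAM-derived carbon and for upstream molecules it is ``None``.
    """

    molecule: str
    route: str
    glucose_fractions: dict[int, dict[int, float]]
    sam_fraction: dict[int, float]
    units: dict[int, tuple[int, int] | None]

    def origin_class(self, carbon: int) -> str:
        if self.sam_fraction.get(carbon, 0.0) > 0.5:
            return "SAM"
        if self.units.get(carbon) is not None:
            return "isoprenoid"
        return "substrate"


@dataclass
class Atlas:
    molecules: dict[str, MoleculeSpec]
    reactions: dict[str, ReactionMap]
    routes: dict[str, PathwayRoute]
    schema_version: int = 1
    source_path: Path | None = None
    _origin_cache: dict = field(default_factory=dict, repr=False)

    def molecule(self, mol_id: str) -> MoleculeSpec:
        try:
            return self.molecules[mol_id]
        except KeyError:
            raise AtlasError(f"unknown molecule: {mol_id}") from None

    def route(self, route_id: str) -> PathwayRoute:
        try:
            return self.routes[route_id]
        except KeyError:
            raise RouteError(f"unknown route: {route_id}") from None


# ---------------------------------------------------------------------------
# validation


def validate_reaction(r: ReactionMap, molecules: dict[str, MoleculeSpec]) -> list[str]:
    """Return invariant violations of one reaction map (empty list = valid).

    Checks: role/molecule/carbon-index referential integrity; every substrate
    carbon consumed exactly once (transition or loss); every product carbon
    produced exactly once (transition or gain) — for merge reactions, product
    carbons may have several parents but incoming weights must sum to 1; and
    total carbon conservation (substrates = products + lost - gained).
    """
    v: list[str] = []
    sub_roles = r.substrate_roles
    prod_roles = r.product_roles
    if len(sub_roles) != len(r.substrates):
        v.append(f"{r.id}: duplicate substrate role")
    if len(prod_roles) != len(r.products):
        v.append(f"{r.id}: duplicate product role")
    for mol, role in r.substrates + r.products:
        if mol not in molecules:
            v.append(f"{r.id}: unknown molecule {mol!r} (role {role})")
    if v:
        return v

    def n_carbons(side: dict[str, str], role: str) -> int:
        return molecules[side[role]].n_carbons

    consumed: dict[tuple[str, int], int] = {}
    produced_weight: dict[tuple[str, int], float] = {}
    produced_count: dict[tuple[str, int], int] = {}

    for t in r.transitions:
        if t.substrate_role not in sub_roles:
            v.append(f"{r.id}: transition references unknown substrate role {t.substrate_role!r}")
            continue
        if t.product_role not in prod_roles:
            v.append(f"{r.id}: transition references unknown product role {t.product_role!r}")
            continue
        if not 1 <= t.substrate_carbon <= n_carbons(sub_roles, t.substrate_role):
            v.append(f"{r.id}: substrate carbon {t.substrate_role}.C{t.substrate_carbon} out of range")
        if not 1 <= t.product_carbon <= n_carbons(prod_roles, t.product_role):
            v.append(f"{r.id}: product carbon {t.product_role}.C{t.product_carbon} out of range")
        consumed[(t.substrate_role, t.substrate_carbon)] = (
            consumed.get((t.substrate_role, t.substrate_carbon), 0) + 1
        )
        key = (t.product_role, t.product_carbon)
        produced_weight[key] = produced_weight.get(key, 0.0) + t.weight
        produced_count[key] = produced_count.get(key, 0) + 1
        if r.kind != "merge" and t.weight != 1.0:
            v.append(f"{r.id}: weighted transition in non-merge reaction")

    for role, carbon, _sink in r.lost_carbons:
        if role not in sub_roles:
            v.append(f"{r.id}: lost carbon references unknown role {role!r}")
            continue
        consumed[(role, carbon)] = consumed.get((role, carbon), 0) + 1
    gained = set()
    for role, carbon, _source in r.gained_carbons:
        if role not in prod_roles:
            v.append(f"{r.id}: gained carbon references unknown role {role!r}")
            continue
        gained.add((role, carbon))

    for role, mol in sub_roles.items():
        for c in range(1, molecules[mol].n_carbons + 1):
            n = consumed.get((role, c), 0)
            if n == 0:
                v.append(f"{r.id}: unmapped substrate carbon {role}.C{c}")
            elif n > 1:
                v.append(f"{r.id}: substrate carbon {role}.C{c} consumed {n} times")
    for role, mol in prod_roles.items():
        for c in range(1, molecules[mol].n_carbons + 1):
            if (role, c) in gained:
                if produced_count.get((role, c)):
                    v.append(f"{r.id}: product carbon {role}.C{c} both gained and mapped")
                continue
            n = produced_count.get((role, c), 0)
            if n == 0:
                v.append(f"{r.id}: unmapped product carbon {role}.C{c}")
            elif r.kind != "merge" and n > 1:
                v.append(f"{r.id}: product carbon {role}.C{c} produced {n} times")
            elif r.kind == "merge" and abs(produced_weight[(role, c)] - 1.0) > 1e-9:
                v.append(
                    f"{r.id}: merge weights into {role}.C{c} sum to "
                    f"{produced_weight[(role, c)]:g}, expected 1"
                )

    if r.kind != "merge":
        total_sub = sum(molecules[m].n_carbons for m, _ in r.substrates)
        total_prod = sum(molecules[m].n_carbons for m, _ in r.products)
        if total_sub != total_prod + len(r.lost_carbons) - len(r.gained_carbons):
            v.append(
                f"{r.id}: carbon balance violated "
                f"({total_sub} substrate != {total_prod} product "
                f"+ {len(r.lost_carbons)} lost - {len(r.gained_carbons)} gained)"
            )
    return v


def _validate_route(route: PathwayRoute, atlas: Atlas) -> list[str]:
    v = []
    available = set(route.inputs)
    for rid in route.reactions:
        if rid not in atlas.reactions:
            v.append(f"route {route.id}: unknown reaction {rid!r}")
            continue
        r = atlas.reactions[rid]
        for mol, role in r.substrates:
            if mol not in available:
                v.append(
                    f"route {route.id}: reaction {rid} needs {mol!r} (role {role}) "
                    "before it is produced"
                )
        available.update(mol for mol, _ in r.products)
    return v


# ---------------------------------------------------------------------------
# parsing


def parse_transition(s: str) -> Transition:
    m = _TRANSITION_RE.match(s)
    if not m:
        raise AtlasParseError(f"malformed transition: {s!r}")
    role_s, c_s, role_p, c_p, w = m.groups()
    return Transition(role_s, int(c_s), role_p, int(c_p), float(w) if w else 1.0)


def _parse_molecule(doc: dict) -> MoleculeSpec:
    try:
        bonds = doc.get("skeleton_bonds")
        hydrogens = doc.get("carbon_hydrogens")
        return MoleculeSpec(
            id=doc["id"],
            n_carbons=int(doc["n_carbons"]),
            numbering=doc.get("numbering", ""),
            formula=doc["formula"],
            skeleton_bonds=tuple(tuple(b) for b in bonds) if bonds else None,
            carbon_hydrogens=tuple(hydrogens) if hydrogens else None,
            side_chain_terminus=doc.get("side_chain_terminus"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise AtlasParseError(f"malformed molecule record {doc.get('id', doc)!r}: {exc}") from exc


def _parse_side(entries: list) -> tuple[tuple[str, str], ...]:
    out = []
    for e in entries:
        out.append((e["molecule"], e["role"]))
    return tuple(out)


def _parse_reaction(doc: dict) -> ReactionMap:
    try:
        return ReactionMap(
            id=doc["id"],
            name=doc.get("name", doc["id"]),
            kind=doc.get("kind", "transition"),
            substrates=_parse_side(doc["substrates"]),
            products=_parse_side(doc["products"]),
            transitions=tuple(parse_transition(t) for t in doc.get("transitions", [])),
            lost_carbons=tuple(
                (e["role"], int(e["carbon"]), e["sink"]) for e in doc.get("lost_carbons", [])
            ),
            gained_carbons=tuple(
                (e["role"], int(e["carbon"]), e["source"]) for e in doc.get("gained_carbons", [])
            ),
            unit_roles=doc.get("unit_roles"),
            role_unit_offset=doc.get("role_unit_offset"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise AtlasParseError(f"malformed reaction record {doc.get('id', doc)!r}: {exc}") from exc


def packaged_atlas_path() -> Path:
    """Path of the atlas shipped with the package."""
    return Path(resources.files("ergolabel.data") / "atlas.yaml")


def load_atlas(path: str | Path | None = None) -> Atlas:
    """Load and fully validate an atlas document.

    Raises :class:`AtlasParseError` on schema problems and
    :class:`AtlasValidationError` (listing every violation) if any reaction
    map or route breaks a carbon-conservation or composition invariant.
    """
    path = Path(path) if path is not None else packaged_atlas_path()
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise AtlasParseError(f"{path}: {exc}") from exc
    if not isinstance(doc, dict) or "molecules" not in doc or "reactions" not in doc:
        raise AtlasParseError(f"{path}: atlas document must contain molecules and reactions")

    molecules = {}
    for m in doc["molecules"]:
        spec = _parse_molecule(m)
        if spec.id in molecules:
            raise AtlasParseError(f"duplicate molecule id {spec.id!r}")
        molecules[spec.id] = spec
    reactions = {}
    for r in doc["reactions"]:
        rx = _parse_reaction(r)
        if rx.id in reactions:
            raise AtlasParseError(f"duplicate reaction id {rx.id!r}")
        reactions[rx.id] = rx
    routes = {}
    for rt in doc.get("routes", []):
        route = PathwayRoute(
            id=rt["id"],
            reactions=tuple(rt["reactions"]),
            inputs=tuple(rt.get("inputs", ("glucose",))),
        )
        routes[route.id] = route

    atlas = Atlas(
        molecules=molecules,
        reactions=reactions,
        routes=routes,
        schema_version=int(doc.get("schema_version", 1)),
        source_path=path,
    )

    violations: list[str] = []
    for spec in molecules.values():
        violations.extend(spec.validate())
    for rx in reactions.values():
        violations.extend(validate_reaction(rx, molecules))
    for route in routes.values():
        violations.extend(_validate_route(route, atlas))
    if violations:
        raise AtlasValidationError("; ".join(violations))
    return atlas


# ---------------------------------------------------------------------------
# provenance tracing

_GLC = "glucose_carbon"


def _forward_distributions(atlas: Atlas, route: PathwayRoute) -> dict[str, list[dict]]:
    """Forward-compose all route reactions.

    Returns, per molecule, a list (index carbon-1) of dictionaries mapping
    source label -> probability.  Source labels are ``("src", molecule, i)``
    for route-input carbons and ``("SAM",)`` for the SAM methyl.  Convergent
    pool splits
    (merge reactions) multiply branch weights, so masses stay normalized.
    """
    pools: dict[str, list[dict]] = {}
    for mol_id in route.inputs:
        mol = atlas.molecule(mol_id)
        pools[mol_id] = [{("src", mol_id, c): 1.0} for c in range(1, mol.n_carbons + 1)]

    for rid in route.reactions:
        r = atlas.reactions[rid]
        sub_roles = r.substrate_roles
        for mol, role in r.substrates:
            if mol not in pools:
                raise RouteError(f"route {route.id}: {mol!r} not available for {rid}")
        new: dict[str, list[dict]] = {}
        for mol, role in r.products:
            new[role] = [dict() for _ in range(atlas.molecule(mol).n_carbons)]
        for t in r.transitions:
            src = pools[sub_roles[t.substrate_role]][t.substrate_carbon - 1]
            dst = new[t.product_role][t.product_carbon - 1]
            for label, p in src.items():
                dst[label] = dst.get(label, 0.0) + p * t.weight
        for role, carbon, source in r.gained_carbons:
            new[role][carbon - 1] = {(source,): 1.0}
        for mol, role in r.products:
            pools[mol] = new[role]
    return pools


def _forward_units(atlas: Atlas, route: PathwayRoute) -> dict[str, list[tuple[int, int] | None]]:
    """Propagate (isoprene unit, IPP position) tags through the route.

    Tags are injected at the reaction carrying ``unit_roles`` (prenyl
    assembly) and re-numbered at reactions carrying ``role_unit_offset``
    (head-to-head condensation), so the six C5 units of the sterol skeleton
    get distinct indices.  Downstream of assembly every carbon has at most
    one tag; SAM-gained carbons have none.
    """
    pools: dict[str, list] = {}
    for mol_id in route.inputs:
        pools[mol_id] = [None] * atlas.molecule(mol_id).n_carbons

    for rid in route.reactions:
        r = atlas.reactions[rid]
        sub_roles = r.substrate_roles
        new: dict[str, list] = {}
        for mol, role in r.products:
            new[role] = [None] * atlas.molecule(mol).n_carbons
        for t in r.transitions:
            if r.unit_roles is not None:
                tag = (r.unit_roles[t.substrate_role], t.substrate_carbon)
            else:
                mol = sub_roles[t.substrate_role]
                if mol not in pools:
                    raise RouteError(f"route {route.id}: {mol!r} not available for {rid}")
                tag = pools[mol][t.substrate_carbon - 1]
                if tag is not None and r.role_unit_offset is not None:
                    tag = (tag[0] + r.role_unit_offset[t.substrate_role], tag[1])
            new[t.product_role][t.product_carbon - 1] = tag
        for mol, role in r.products:
            pools[mol] = new[role]
    return pools


def trace_origin(atlas: Atlas, target: str, route: str | PathwayRoute) -> CarbonOrigin:
    """Trace every carbon of ``target`` back to glucose carbons on ``route``.

    Deterministic for a fixed atlas: the result is the exact backward
    composition of the packaged transitions, with branch probabilities
    multiplied along convergent pool splits (the triose merge).
    """
    rt = atlas.route(route) if isinstance(route, str) else route
    cache_key = (rt.id, id(atlas))
    if cache_key not in atlas._origin_cache:
        atlas._origin_cache[cache_key] = (
            _forward_distributions(atlas, rt),
            _forward_units(atlas, rt),
        )
    dists, units = atlas._origin_cache[cache_key]
    if target not in dists:
        raise RouteError(f"molecule {target!r} is not reachable on route {rt.id}")
    mol = atlas.molecule(target)
    glucose_fractions: dict[int, dict[int, float]] = {}
    sam_fraction: dict[int, float] = {}
    unit_map: dict[int, tuple[int, int] | None] = {}
    primary_input = rt.inputs[0]
    for c in range(1, mol.n_carbons + 1):
        dist = dists[target][c - 1]
        glucose_fractions[c] = {
            label[2]: p
            for label, p in dist.items()
            if label[0] == "src" and label[1] == primary_input
        }
        sam_fraction[c] = sum(p for label, p in dist.items() if label[0] == SAM_SOURCE)
        unit_map[c] = units[target][c - 1]
    return CarbonOrigin(
        molecule=target,
        route=rt.id,
        glucose_fractions=glucose_fractions,
        sam_fraction=sam_fraction,
        units=unit_map,
    )


def unit_positions(origin: CarbonOrigin) -> dict[int, tuple[int, int] | str]:
    """Map each carbon to its (isoprene unit, IPP position), or ``"SAM"``.

    The decomposition depends only on prenyl assembly onward, so it is
    identical whichever route produced the IPP/DMAPP pool.
    """
    out: dict[int, tuple[int, int] | str] = {}
    for c, tag in origin.units.items():
        if origin.origin_class(c) == "SAM":
            out[c] = SAM_SOURCE
        elif tag is not None:
            out[c] = tag
    return out
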