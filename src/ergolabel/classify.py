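"""Pathway-of-origin classification of observed product-ion mass shifts.

An observation is a neutral/labeled nominal m/z pair for one product ion.
Its integer shift is compared with the number of theoretically labelable
carbon positions the fragment retains under each pathway hypothesis; a
pathway verdict requires the shift to be explained by exactly one
hypothesis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .atlas import Atlas
from .fragments import (
    FragmentAnnotation,
    FragmentCandidate,
    FragmentError,
    enumerate_fragments,
    format_carbon_set,
)
from .labeling import Hypothesis, TracerSpec, labelable_positions, propagate

__all__ = [
    "ShiftObservation",
    "ClassificationRecord",
    "ConditionSummary",
    "ResolutionError",
    "classify",
    "verdict_from_counts",
    "summarize",
    "compare_conditions",
    "read_observations",
    "write_classification_tsv",
]

VERDICTS = ("MVA", "MEP", "ambiguous", "unexplained")


class ResolutionError(LookupError):
    """No fragment structure source resolvable for an observed mass."""


@dataclass(frozen=True)
class ShiftObservation:
    neutral_mz: int
    labeled_mz: int
    condition: str = ""

    def __post_init__(self):
        if self.labeled_mz < self.neutral_mz:
            raise ValueError(
                f"labeled m/z {self.labeled_mz} below neutral m/z {self.neutral_mz}"
            )

    @property
    def shift(self) -> int:
        return self.labeled_mz - self.neutral_mz


@dataclass(frozen=True)
class ClassificationRecord:
    observation: ShiftObservation
    mode: str  # annotated | top-candidate | any-candidate
    counts: dict  # hypothesis -> predicted count (or attainable count set)
    candidate_used: object  # FragmentAnnotation | FragmentCandidate | list
    verdict: str

    def to_row(self) -> dict:
        obs = self.observation
        used = self.candidate_used
        if isinstance(used, (FragmentAnnotation, FragmentCandidate)):
            carbons = format_carbon_set(used.carbons)
        else:
            carbons = ";".join(format_carbon_set(c.carbons) for c in used)
        counts = {
            f"count_{h}": (v if isinstance(v, int) else format_carbon_set(v))
            for h, v in self.counts.items()
        }
        return {
            "neutral_mz": obs.neutral_mz,
            "labeled_mz": obs.labeled_mz,
            "shift": obs.shift,
            "condition": obs.condition,
            "mode": self.mode,
            **counts,
            "fragment_carbons": carbons,
            "verdict": self.verdict,
        }


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n_observations: int
    verdict_counts: dict

    def __post_init__(self):
        if sum(self.verdict_counts.values()) != self.n_observations:
            raise ValueError("verdict counts must sum to n_observations")


def _labelable_sets(atlas: Atlas, hypotheses, tracer: TracerSpec, molecule: str):
    return {
        h.route: labelable_positions(propagate(atlas, tracer, h, molecule))
        for h in hypotheses
    }


def _verdict(shift: int, explained: dict[str, bool]) -> str:
    hits = [h for h, ok in explained.items() if ok]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        return "ambiguous"
    return "unexplained"


def verdict_from_counts(shift: int, counts: dict[str, int], allow_partial: bool = False) -> str:
    """Pure verdict function: a hypothesis explains the shift iff the shift
    equals its predicted count (or, with ``allow_partial``, lies in
    ``1..count``); exactly one explaining hypothesis names the pathway,
    several is ambiguous, none is unexplained."""

    def matches(c: int) -> bool:
        return (1 <= shift <= c) if allow_partial else shift == c

    return _verdict(shift, {h: matches(c) for h, c in counts.items()})


def classify(
    atlas: Atlas,
    obs: ShiftObservation,
    annotations: list[FragmentAnnotation] | None = None,
    mode: str = "auto",
    hypotheses: tuple[Hypothesis, Hypothesis] = (Hypothesis("MVA"), Hypothesis("MEP")),
    tracer: TracerSpec | None = None,
    molecule: str = "ergosterol",
    allow_partial: bool = False,
    max_cleavages: int = 3,
) -> ClassificationRecord:
    """Classify one observed neutral->labeled shift pair.

    Structure source: ``annotated`` uses the annotation matching the neutral
    m/z; ``top-candidate`` uses the best-ranked enumerated structure;
    ``any-candidate`` tests the shift against the attainable count set over
    all enumerated structures.  ``auto`` (default) prefers an annotation when
    one covers the mass and falls back to top-candidate.

    Match criterion: the observed shift must equal the predicted labeled-
    position count (full incorporation).  With ``allow_partial`` a shift is
    also explained when 1 <= shift <= count (partial incorporation of a
    multiply labelable fragment).
    """
    tracer = tracer or TracerSpec()
    parent = atlas.molecule(molecule)
    labelable = _labelable_sets(atlas, hypotheses, tracer, molecule)

    annotation = None
    if annotations:
        hit = [a for a in annotations if a.nominal_mz == obs.neutral_mz]
        if hit:
            annotation = hit[0]
    if mode == "auto":
        mode = "annotated" if annotation is not None else "top-candidate"

    def matches(shift: int, count: int) -> bool:
        if allow_partial:
            return 1 <= shift <= count
        return shift == count

    if mode == "annotated":
        if annotation is None:
            raise ResolutionError(f"no annotation for m/z {obs.neutral_mz}")
        structure = annotation
        counts = {h: len(labelable[h] & annotation.carbons) for h in labelable}
        explained = {h: matches(obs.shift, c) for h, c in counts.items()}
    elif mode in ("top-candidate", "any-candidate"):
        candidates = enumerate_fragments(parent, obs.neutral_mz, max_cleavages)
        if not candidates:
            raise ResolutionError(
                f"no fragment structure enumerable for m/z {obs.neutral_mz}"
            )
        if mode == "top-candidate":
            structure = candidates[0]
            counts = {h: len(labelable[h] & structure.carbons) for h in labelable}
            explained = {h: matches(obs.shift, c) for h, c in counts.items()}
        else:
            structure = candidates
            counts = {
                h: frozenset(len(labelable[h] & c.carbons) for c in candidates)
                for h in labelable
            }
            explained = {
                h: any(matches(obs.shift, c) for c in attainable)
                for h, attainable in counts.items()
            }
    else:
        raise ValueError(f"unknown classification mode: {mode!r}")

    return ClassificationRecord(
        observation=obs,
        mode=mode,
        counts=counts,
        candidate_used=structure,
        verdict=_verdict(obs.shift, explained),
    )


def summarize(records: list[ClassificationRecord]) -> dict[str, ConditionSummary]:
    """Per-condition verdict tallies (counts always sum to inputs)."""
    by_condition: dict[str, list[ClassificationRecord]] = {}
    for rec in records:
        by_condition.setdefault(rec.observation.condition, []).append(rec)
    out = {}
    for condition, recs in by_condition.items():
        counts = {v: 0 for v in VERDICTS}
        for rec in recs:
            counts.setdefault(rec.verdict, 0)
            counts[rec.verdict] += 1
        out[condition] = ConditionSummary(
            condition=condition, n_observations=len(recs), verdict_counts=counts
        )
    return out


def compare_conditions(a: ConditionSummary, b: ConditionSummary) -> dict:
    """Per-verdict deltas between two condition summaries plus flags for
    condition-specific pathway support."""
    verdicts = sorted(set(a.verdict_counts) | set(b.verdict_counts))
    deltas = {
        v: a.verdict_counts.get(v, 0) - b.verdict_counts.get(v, 0) for v in verdicts
    }
    flags = []
    for pathway in ("MVA", "MEP"):
        d = deltas.get(pathway, 0)
        if d > 0:
            flags.append(f"{pathway} support higher in condition {a.condition!r} (+{d})")
        elif d < 0:
            flags.append(f"{pathway} support higher in condition {b.condition!r} (+{-d})")
    table = pd.DataFrame(
        {
            a.condition: [a.verdict_counts.get(v, 0) for v in verdicts],
            b.condition: [b.verdict_counts.get(v, 0) for v in verdicts],
            "delta": [deltas[v] for v in verdicts],
        },
        index=verdicts,
    )
    return {"deltas": deltas, "flags": flags, "table": table}


# ---------------------------------------------------------------------------
# I/O


def read_observations(path: str | Path) -> list[ShiftObservation]:
    """Read an observation TSV (columns neutral_mz, labeled_mz, condition)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = {"neutral_mz", "labeled_mz"} - set(df.columns)
    if missing:
        raise FragmentError(f"{path}: missing observation columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ShiftObservation(
                neutral_mz=int(row["neutral_mz"]),
                labeled_mz=int(row["labeled_mz"]),
                condition=str(row.get("condition", "")),
            )
        )
    return out


def write_classification_tsv(
    records: list[ClassificationRecord], path: str | Path, header_lines: list[str] | None = None
) -> None:
    df = pd.DataFrame([r.to_row() for r in records])
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_summary_json(
    summaries: dict[str, ConditionSummary], path: str | Path, metadata: dict | None = None
) -> None:
    doc = {
        "conditions": {
            cond: {
                "n_observations": s.n_observations,
                "verdicts": s.verdict_counts,
            }
            for cond, s in summaries.items()
        }
    }
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
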