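"""Set-algebra combination of the two engines' predictions.

Given prediction sets A (patch engine) and B (whole-surface engine), the
ensemble reports their Union (explore as many associated residues as
possible → higher sensitivity), their Intersection (mutual verification →
higher reliability when non-empty), and the Consistency

    Consistency = |A ∩ B| / |A ∪ B|,

interpreted in four bands: ≥ 0.5 almost certain, [0.25, 0.5) likely,
(0, 0.25) possible, and 0 a failed mutual verification (by convention the
Consistency of two empty sets is 0).
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidate_assembly import PredictionSet

BANDS = ("almost_certain", "likely", "possible", "failed")


class EnsembleInputError(ValueError):
    pass


def classify_consistency(c: float) -> str:
    """Band for a consistency value in [0, 1]; boundaries are inclusive on
    the upper side (0.5 → almost_certain, 0.25 → likely, 0 → failed)."""
    if not 0.0 <= c <= 1.0:
        raise EnsembleInputError(f"consistency {c} outside [0, 1]")
    if c == 0.0:
        return "failed"
    if c >= 0.5:
        return "almost_certain"
    if c >= 0.25:
        return "likely"
    return "possible"


@dataclass(frozen=True)
class EnsembleResult:
    set_a: PredictionSet
    set_b: PredictionSet
    intersection: PredictionSet
    union: PredictionSet
    consistency: float
    band: str


def combine(a: PredictionSet, b: PredictionSet) -> EnsembleResult:
    """Union, Intersection, Consistency and band for two prediction sets.

    Both sets must refer to the same antigen chain(s); an empty set places
    no constraint.  The inclusion–exclusion identity
    |A| + |B| = |A∩B| + |A∪B| is asserted on every call.
    """
    if a.chain_ids and b.chain_ids and a.chain_ids != b.chain_ids:
        raise EnsembleInputError(
            f"prediction sets reference different chains: "
            f"{sorted(a.chain_ids)} vs {sorted(b.chain_ids)}"
        )
    inter = a.residues & b.residues
    union = a.residues | b.residues
    assert len(a.residues) + len(b.residues) == len(inter) + len(union)
    consistency = len(inter) / len(union) if union else 0.0
    return EnsembleResult(
        set_a=a,
        set_b=b,
        intersection=PredictionSet(inter, source="intersection"),
        union=PredictionSet(union, source="union"),
        consistency=consistency,
        band=classify_consistency(consistency),
    )


def _fmt_keys(keys) -> str:
    return ", ".join(f"{c}:{n}{i}" for c, n, i in sorted(keys)) or "(none)"


def format_compare_report(result: EnsembleResult) -> str:
    """Two-box text listing of both engines plus Intersection and Union."""
    lines = [
        f"[{result.set_a.source or 'A'}] {len(result.set_a)} residues",
        f"  {_fmt_keys(result.set_a.residues)}",
        f"[{result.set_b.source or 'B'}] {len(result.set_b)} residues",
        f"  {_fmt_keys(result.set_b.residues)}",
        "",
        f"Intersection ({len(result.intersection)} residues):",
        f"  {_fmt_keys(result.intersection.residues)}",
        f"Union ({len(result.union)} residues):",
        f"  {_fmt_keys(result.union.residues)}",
        "",
        f"Consistency = {result.consistency:.3f}  [{result.band}]",
    ]
    return "\n".join(lines) + "\n"
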