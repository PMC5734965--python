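"""Synthetic name pairs with controlled edit structure.

Generates letter-string names emulating the proprietary-name population
the screening analysis assumes — uppercase A-Z strings of length 5-13 —
and variants related to them by a controlled number of substitutions,
adjacent transpositions, insertions and deletions.  Because the true edit
recipe of each pair is recorded, every stage of the scoring pipeline can
be property-tested without any real formulary: e.g. on a repeat-free base,
one substitution (with a letter absent from the base) must score exactly
(n-1)/n with markers off, and one adjacent transposition must score
(n - 2 + 2*exp(-1/sigma))/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import CanonicalName, ValidationError

__all__ = ["EditSpec", "CohortSpec", "EditOp", "random_name", "mutate", "generate_cohort"]

_ALPHABET = [chr(ord("A") + i) for i in range(26)]


@dataclass(frozen=True)
class EditSpec:
    """How many edits of each kind relate a variant to its base."""

    n_substitutions: int = 0
    n_adjacent_transpositions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    @property
    def total(self) -> int:
        return (
            self.n_substitutions
            + self.n_adjacent_transpositions
            + self.n_insertions
            + self.n_deletions
        )


@dataclass(frozen=True)
class EditOp:
    """One applied edit: kind, 0-based position, and letters involved."""

    kind: str
    position: int
    detail: str


@dataclass(frozen=True)
class CohortSpec:
    """A reproducible cohort of (base, variant) pairs.

    Lengths are drawn from ``length_distribution`` (a mapping length ->
    probability; default uniform over 5-13, the typical proprietary-name
    range).  Edit specs from ``edit_grid`` are assigned round-robin so the
    cohort spans the grid evenly.  ``unique_letters`` samples bases without
    letter repetition, the regime where match values have closed forms.
    """

    n_pairs: int
    edit_grid: Sequence[EditSpec] = (EditSpec(n_substitutions=1),)
    length_distribution: Mapping[int, float] | None = None
    seed: int = 0
    unique_letters: bool = False

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if not self.edit_grid:
            raise ValidationError("edit_grid must be non-empty")
        if self.length_distribution is not None:
            if not self.length_distribution:
                raise ValidationError("length_distribution must be non-empty")
            for length, p in self.length_distribution.items():
                if not (1 <= length <= 30) or p < 0:
                    raise ValidationError("length_distribution entries out of range")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_name(
    length: int,
    seed: int | np.random.Generator = 0,
    unique_letters: bool = False,
) -> CanonicalName:
    """A name of i.i.d. uniform letters (or a no-repeat sample); seeded."""
    if not (1 <= length <= 30):
        raise ValidationError(f"length must be in [1, 30], got {length}")
    if unique_letters and length > 26:
        raise ValidationError("unique_letters needs length <= 26")
    rng = _as_rng(seed)
    letters = rng.choice(_ALPHABET, size=length, replace=not unique_letters)
    return CanonicalName.from_text("".join(letters))


def _fresh_letters(rng: np.random.Generator, forbidden: set[str], k: int) -> list[str]:
    pool = [c for c in _ALPHABET if c not in forbidden]
    if len(pool) < k:
        raise ValidationError("not enough unused letters for the requested edits")
    return list(rng.choice(pool, size=k, replace=False))


def mutate(
    base: CanonicalName,
    spec: EditSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[CanonicalName, list[EditOp]]:
    """Apply a controlled edit recipe to ``base``; returns (variant, log).

    Edits are applied in a fixed order — deletions, substitutions,
    adjacent transpositions, insertions — at seed-determined positions.
    Substituted-in and inserted letters are drawn from letters absent from
    the base (and from each other), so a substitution can never create an
    accidental match; transposition sites are chosen non-overlapping with
    unequal letters so each one is a real edit.
    """
    if spec.total > base.length - 1:
        raise ValidationError(
            f"spec with {spec.total} edits infeasible for length {base.length}"
        )
    rng = _as_rng(seed)
    letters = list(base.text)
    log: list[EditOp] = []

    if spec.n_deletions:
        if spec.n_deletions >= len(letters):
            raise ValidationError("cannot delete every letter")
        pos = sorted(rng.choice(len(letters), size=spec.n_deletions, replace=False))
        for p in reversed(pos):
            log.append(EditOp("deletion", int(p), letters[p]))
            del letters[p]

    forbidden = set(base.text)
    if spec.n_substitutions:
        if spec.n_substitutions > len(letters):
            raise ValidationError("more substitutions than remaining letters")
        pos = rng.choice(len(letters), size=spec.n_substitutions, replace=False)
        fresh = _fresh_letters(rng, forbidden, spec.n_substitutions)
        for p, new in zip(pos, fresh, strict=True):
            log.append(EditOp("substitution", int(p), f"{letters[p]}->{new}"))
            letters[int(p)] = new
            forbidden.add(new)

    if spec.n_adjacent_transpositions:
        used: set[int] = set()
        candidates = [
            i for i in range(len(letters) - 1) if letters[i] != letters[i + 1]
        ]
        order = rng.permutation(len(candidates))
        done = 0
        for idx in order:
            i = candidates[idx]
            if done == spec.n_adjacent_transpositions:
                break
            if i in used or i + 1 in used or letters[i] == letters[i + 1]:
                continue
            letters[i], letters[i + 1] = letters[i + 1], letters[i]
            log.append(EditOp("transposition", i, f"{letters[i + 1]}<->{letters[i]}"))
            used.update((i, i + 1))
            done += 1
        if done < spec.n_adjacent_transpositions:
            raise ValidationError("not enough non-overlapping transposition sites")

    if spec.n_insertions:
        fresh = _fresh_letters(rng, forbidden, spec.n_insertions)
        for new in fresh:
            p = int(rng.integers(0, len(letters) + 1))
            letters.insert(p, new)
            log.append(EditOp("insertion", p, new))
            forbidden.add(new)

    return CanonicalName.from_text("".join(letters)), log


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Emit ``n_pairs`` (base, variant) rows spanning the edit grid.

    Columns: row_id, base, variant, and the four edit counts of the true
    recipe, so property assertions can condition on it.  Fully
    deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.length_distribution is None:
        lengths = list(range(5, 14))
        probs = np.full(len(lengths), 1.0 / len(lengths))
    else:
        lengths = sorted(spec.length_distribution)
        probs = np.array([spec.length_distribution[l] for l in lengths], float)
        probs = probs / probs.sum()
    rows = []
    for i in range(spec.n_pairs):
        edit = spec.edit_grid[i % len(spec.edit_grid)]
        length = int(rng.choice(lengths, p=probs))
        length = max(length, edit.total + 1, 1 + edit.n_deletions)
        base = random_name(length, rng, unique_letters=spec.unique_letters)
        variant, _ = mutate(base, edit, rng)
        rows.append(
            {
                "row_id": i + 1,
                "base": base.text,
                "variant": variant.text,
                "n_substitutions": edit.n_substitutions,
                "n_adjacent_transpositions": edit.n_adjacent_transpositions,
                "n_insertions": edit.n_insertions,
                "n_deletions": edit.n_deletions,
            }
        )
    return pd.DataFrame(rows)
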