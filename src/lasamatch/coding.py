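"""Spatial-coding match values for letter strings.

A name is represented as an ordered sequence of letter tokens, each letter
node carrying a position activity drawn from a monotonically descending
series.  Comparing an input string against a stored word produces one
signal-weight difference per shared letter token,

    d_ji = s_j - z_ji,

where ``s_j`` is the activity of the j-th letter node in the input's code
and ``z_ji`` is the stored word's weight for that letter.  Each difference
contributes a Gaussian difference function

    f_ji(x) = exp(-(d_ji - x)^2 / sigma),

and the superposition F_i(x) = sum_j f_ji(x) peaks where the largest number
of letters agree on a common positional displacement.  The match value

    M_i = max_x F_i(x) / l_i

normalises the peak by the comparison-letter count l_i and lies in [0, 1].
``sigma`` is the letter-position uncertainty (default 3): larger values
forgive larger positional displacements, which is what makes the measure
lenient to adjacent letter transpositions relative to substitutions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "LetterToken",
    "CanonicalName",
    "CodedToken",
    "SpatialCode",
    "MatchParams",
    "BoundPair",
    "BindingResult",
    "SuperpositionProfile",
    "MatchScore",
    "encode",
    "bind_letters",
    "find_peak",
    "match_value",
    "grid_scores",
]

Series = Literal["descending_unit", "ascending_unit"]
DenominatorMode = Literal["word", "input", "longer", "shorter", "mean"]
WordRole = Literal["first_name", "second_name"]
BindingMode = Literal["in_order", "optimal"]

_SERIES = ("descending_unit", "ascending_unit")
_DENOMINATORS = ("word", "input", "longer", "shorter", "mean")
_ROLES = ("first_name", "second_name")
_BINDINGS = ("in_order", "optimal")

#: hard cap on enumerated per-letter assignments in ``optimal`` binding
_MAX_ASSIGNMENTS = 200_000


class ValidationError(ValueError):
    """Raised for invalid names, parameters, or malformed inputs."""


@dataclass(frozen=True)
class LetterToken:
    """One letter occurrence: the letter plus its 1-based occurrence index."""

    letter: str
    occurrence: int

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or not ("A" <= self.letter <= "Z"):
            raise ValidationError(f"letter token must be A-Z, got {self.letter!r}")
        if self.occurrence < 1:
            raise ValidationError("occurrence index is 1-based")


@dataclass(frozen=True)
class CanonicalName:
    """A proprietary name reduced to an ordered uppercase letter sequence.

    ``raw_label`` keeps the label exactly as supplied (it may contain the
    registered-trademark sign, hyphens, mixed case); ``letters`` holds one
    token per A-Z letter with its occurrence index, so repeated letters are
    distinguishable channels.
    """

    raw_label: str
    letters: tuple[LetterToken, ...]

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValidationError(
                f"name {self.raw_label!r} contains no letters after canonicalization"
            )
        seen: dict[str, int] = {}
        for tok in self.letters:
            seen[tok.letter] = seen.get(tok.letter, 0) + 1
            if tok.occurrence != seen[tok.letter]:
                raise ValidationError(
                    f"occurrence index of {tok.letter} in {self.raw_label!r} "
                    f"must be {seen[tok.letter]}, got {tok.occurrence}"
                )

    @classmethod
    def from_text(cls, text: str, raw_label: str | None = None) -> "CanonicalName":
        """Build from an uppercase A-Z string (already canonical)."""
        counts: dict[str, int] = {}
        tokens = []
        for ch in text:
            counts[ch] = counts.get(ch, 0) + 1
            tokens.append(LetterToken(ch, counts[ch]))
        return cls(raw_label if raw_label is not None else text, tuple(tokens))

    @property
    def text(self) -> str:
        return "".join(t.letter for t in self.letters)

    @property
    def length(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class CodedToken:
    token: LetterToken
    value: float


@dataclass(frozen=True)
class SpatialCode:
    """Per-token position activities for one name under one code series."""

    tokens: tuple[CodedToken, ...]
    series: str

    def __post_init__(self) -> None:
        values = [t.value for t in self.tokens]
        if any(b >= a for a, b in zip(values, values[1:], strict=False)):
            raise ValidationError("position values must be strictly descending")

    @property
    def length(self) -> int:
        return len(self.tokens)

    def activity(self) -> dict[tuple[str, int], float]:
        """Map (letter, occurrence) -> position activity."""
        return {(t.token.letter, t.token.occurrence): t.value for t in self.tokens}


@dataclass(frozen=True)
class MatchParams:
    """Conventions of one match computation.

    sigma
        Letter-position uncertainty; width of the Gaussian difference
        functions.  Default 3.
    end_markers
        When on, two extra channels compare the first letters and the last
        letters of the two names; on letter equality each contributes the
        positional difference of the two end tokens as a center (0 for
        equal-length names, nothing on inequality) and the pair adds 2 to
        l_i.
    denominator_mode
        Which letter count normalises the peak: the stored word's
        (``word``, default), the input's, the longer/shorter of the two, or
        their arithmetic mean.
    word_role
        Which member of a pair plays the stored word node: the first name
        of the pair (default; the local proprietary name in a local-vs-
        overseas table) or the second.
    binding_mode
        ``in_order`` pairs the k-th occurrence of a letter with the k-th
        occurrence in the input; ``optimal`` searches per-letter one-to-one
        assignments for the one maximising the match value.
    code_series
        ``descending_unit`` gives the p-th of n letters activity n-p+1;
        ``ascending_unit`` codes p and negates to stay descending.  The two
        are equivalent up to a shift/reflection of the difference multiset
        and give identical match values.
    sigma_squared_exponent
        Off by default: the exponent divides by sigma itself.  When on it
        divides by sigma**2 instead (an alternative normalisation some
        implementations use).
    """

    sigma: float = 3.0
    end_markers: bool = True
    denominator_mode: str = "word"
    word_role: str = "first_name"
    binding_mode: str = "in_order"
    code_series: str = "descending_unit"
    sigma_squared_exponent: bool = False

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValidationError(f"sigma must be a positive finite real, got {self.sigma}")
        for value, allowed, name in (
            (self.denominator_mode, _DENOMINATORS, "denominator_mode"),
            (self.word_role, _ROLES, "word_role"),
            (self.binding_mode, _BINDINGS, "binding_mode"),
            (self.code_series, _SERIES, "code_series"),
        ):
            if value not in allowed:
                raise ValidationError(f"{name} must be one of {allowed}, got {value!r}")

    @property
    def exponent_scale(self) -> float:
        """What divides the squared deviation inside the Gaussian."""
        return self.sigma**2 if self.sigma_squared_exponent else self.sigma


@dataclass(frozen=True)
class BoundPair:
    letter: str
    occurrence: int
    word_position: int
    input_position: int
    d: float


@dataclass(frozen=True)
class BindingResult:
    """Signal-weight differences between a stored word and an input."""

    bound: tuple[BoundPair, ...]
    unbound_word_tokens: tuple[LetterToken, ...]
    marker_differences: tuple[float, ...]
    l_i: int

    @property
    def centers(self) -> tuple[float, ...]:
        """Gaussian centers: one per bound letter plus marker channels."""
        return tuple(p.d for p in self.bound) + self.marker_differences


@dataclass(frozen=True)
class SuperpositionProfile:
    centers: tuple[float, ...]
    sigma: float
    x_star: float
    f_star: float


@dataclass(frozen=True)
class MatchScore:
    value: float
    l_i: float
    params: MatchParams
    profile: SuperpositionProfile
    binding: BindingResult

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def encode(name: CanonicalName, series: str = "descending_unit") -> SpatialCode:
    """Assign each letter token a position activity from a descending series.

    ``descending_unit`` gives the token at 1-based ordinal ``p`` of an
    n-letter name the value ``n - p + 1`` (equivalently, its position
    counted from the end).  ``ascending_unit`` assigns ``p`` and negates,
    preserving the descending invariant; the two series give identical
    match values because the difference multiset only reflects and shifts.
    """
    if series not in _SERIES:
        raise ValidationError(f"unknown code series {series!r}")
    n = name.length
    if series == "descending_unit":
        values = [float(n - p) for p in range(n)]
    else:
        values = [-float(p + 1) for p in range(n)]
    return SpatialCode(
        tuple(CodedToken(tok, val) for tok, val in zip(name.letters, values, strict=True)),
        series,
    )


def _marker_differences(word: SpatialCode, inp: SpatialCode) -> tuple[float, ...]:
    """End-marker channels: first-vs-first and last-vs-last letters.

    A channel fires only on letter equality and contributes the
    signal-weight difference of the two end tokens under the active code
    (0 whenever the names have equal length).  Computing the marker d the
    same way as letter ds keeps the whole center multiset in one frame,
    which is what makes match values invariant to code shifts and
    identical across the two code series.
    """
    diffs = []
    if word.tokens[0].token.letter == inp.tokens[0].token.letter:
        diffs.append(inp.tokens[0].value - word.tokens[0].value)
    if word.tokens[-1].token.letter == inp.tokens[-1].token.letter:
        diffs.append(inp.tokens[-1].value - word.tokens[-1].value)
    return tuple(diffs)


def _in_order_bound(word: SpatialCode, inp: SpatialCode) -> tuple[list[BoundPair], list[LetterToken]]:
    input_activity = inp.activity()
    input_position = {
        (t.token.letter, t.token.occurrence): p + 1 for p, t in enumerate(inp.tokens)
    }
    bound: list[BoundPair] = []
    unbound: list[LetterToken] = []
    for p, coded in enumerate(word.tokens, start=1):
        key = (coded.token.letter, coded.token.occurrence)
        if key in input_activity:
            bound.append(
                BoundPair(
                    letter=coded.token.letter,
                    occurrence=coded.token.occurrence,
                    word_position=p,
                    input_position=input_position[key],
                    d=input_activity[key] - coded.value,
                )
            )
        else:
            unbound.append(coded.token)
    return bound, unbound


def _optimal_bound(
    word: SpatialCode,
    inp: SpatialCode,
    markers: tuple[float, ...],
    sigma: float,
) -> tuple[list[BoundPair], list[LetterToken]]:
    """Per-letter-type one-to-one assignment maximising the peak.

    l_i is fixed by the word length and the marker setting, so maximising
    the match value is exactly maximising the superposition peak.
    """
    by_letter_word: dict[str, list[tuple[int, CodedToken]]] = {}
    by_letter_input: dict[str, list[tuple[int, CodedToken]]] = {}
    for p, t in enumerate(word.tokens, start=1):
        by_letter_word.setdefault(t.token.letter, []).append((p, t))
    for p, t in enumerate(inp.tokens, start=1):
        by_letter_input.setdefault(t.token.letter, []).append((p, t))

    shared = [lt for lt in by_letter_word if lt in by_letter_input]
    # per shared letter: all maximal injective matchings word-occ -> input-occ
    per_letter_options: list[list[tuple[tuple[int, int], ...]]] = []
    total = 1
    for lt in shared:
        w_toks = by_letter_word[lt]
        i_toks = by_letter_input[lt]
        k = min(len(w_toks), len(i_toks))
        options = []
        for w_sel in itertools.combinations(range(len(w_toks)), k):
            for i_sel in itertools.permutations(range(len(i_toks)), k):
                options.append(tuple(zip(w_sel, i_sel, strict=True)))
        per_letter_options.append(options)
        total *= len(options)
        if total > _MAX_ASSIGNMENTS:
            raise ValidationError(
                "optimal binding: too many per-letter assignments to enumerate "
                f"(> {_MAX_ASSIGNMENTS}); use in_order binding"
            )

    def build(combo) -> list[BoundPair]:
        bound: list[BoundPair] = []
        for lt, matching in zip(shared, combo, strict=True):
            w_toks = by_letter_word[lt]
            i_toks = by_letter_input[lt]
            for wi, ii in matching:
                wp, wtok = w_toks[wi]
                ip, itok = i_toks[ii]
                bound.append(
                    BoundPair(
                        letter=lt,
                        occurrence=wtok.token.occurrence,
                        word_position=wp,
                        input_position=ip,
                        d=itok.value - wtok.value,
                    )
                )
        return bound

    if total == 1:
        # a single feasible assignment (no shared letter repeats): no search
        best_bound = build([opts[0] for opts in per_letter_options])
    else:
        best: tuple[float, list[BoundPair]] | None = None
        for combo in itertools.product(*per_letter_options):
            bound = build(combo)
            _, f_star = find_peak([b.d for b in bound] + list(markers), sigma)
            if best is None or f_star > best[0] + 1e-12:
                best = (f_star, bound)
        assert best is not None
        best_bound = best[1]
    bound = sorted(best_bound, key=lambda b: b.word_position)
    matched = {(b.letter, b.occurrence) for b in bound}
    unbound = [t.token for t in word.tokens if (t.token.letter, t.token.occurrence) not in matched]
    return bound, unbound


def bind_letters(
    word: SpatialCode,
    input_code: SpatialCode,
    mode: str = "in_order",
    end_markers: bool = True,
    sigma: float = 3.0,
) -> BindingResult:
    """Pair each word letter token with at most one same-letter input token.

    Each bound pair contributes ``d = input activity - word weight``; word
    tokens without a partner are listed unbound and contribute no Gaussian
    but still count in ``l_i``.  ``sigma`` is only consulted in ``optimal``
    mode, where candidate assignments are ranked by the peak they produce.
    """
    if mode not in _BINDINGS:
        raise ValidationError(f"binding mode must be one of {_BINDINGS}, got {mode!r}")
    if not word.tokens or not input_code.tokens:
        raise ValidationError("both codes must be non-empty")
    markers = _marker_differences(word, input_code) if end_markers else ()
    if mode == "in_order":
        bound, unbound = _in_order_bound(word, input_code)
    else:
        bound, unbound = _optimal_bound(word, input_code, markers, sigma)
    l_i = word.length + (2 if end_markers else 0)
    return BindingResult(tuple(bound), tuple(unbound), markers, l_i)


def find_peak(centers: Sequence[float], sigma: float) -> tuple[float, float]:
    """Global maximum of ``F(x) = sum_j exp(-(d_j - x)^2 / sigma)``.

    Returns ``(x_star, f_star)``.  The maximum of a positive Gaussian
    mixture lies in the convex hull of its centers, so the search is
    confined to ``[min(d), max(d)]``: a coarse grid (step well below the
    component width ``sqrt(sigma/2)``) brackets every local maximum, the
    brackets are narrowed by vectorised grid-zoom rounds, and the winner
    is polished by bounded scalar minimisation.  Ties are broken toward
    the smallest ``x``.  Empty ``centers`` give ``(0, 0)``.
    """
    if not (sigma > 0 and math.isfinite(sigma)):
        raise ValidationError(f"sigma must be a positive finite real, got {sigma}")
    if len(centers) == 0:
        return 0.0, 0.0
    uniq: dict[float, int] = {}
    for c in centers:
        c = float(c)
        uniq[c] = uniq.get(c, 0) + 1
    if len(uniq) == 1:
        (c, n), = uniq.items()
        return c, float(n)
    cs = np.fromiter(uniq.keys(), dtype=float)
    ws = np.fromiter(uniq.values(), dtype=float)
    lo, hi = float(cs.min()), float(cs.max())
    step = min(0.05, math.sqrt(sigma / 2.0) / 8.0)
    grid = np.arange(lo, hi + step, step)
    grid[-1] = min(grid[-1], hi)

    def evaluate(xs: np.ndarray) -> np.ndarray:
        return np.exp(-((cs[:, None] - xs[None, :]) ** 2) / sigma).T @ ws

    f = evaluate(grid)
    # every interior local maximum plus both endpoints is a candidate bracket
    interior = np.flatnonzero((f[1:-1] >= f[:-2]) & (f[1:-1] >= f[2:])) + 1
    candidates = sorted({0, len(grid) - 1, *interior.tolist()})
    xs, fs = grid[candidates], f[candidates]
    # zoom every candidate bracket in lockstep; collapse only at the end so
    # two nearly-equal modes are both tracked to full precision
    width = step
    offsets = np.linspace(-1.0, 1.0, 9)
    while width > 1e-8:
        pts = np.clip(xs[:, None] + width * offsets[None, :], lo, hi)
        vals = evaluate(pts.ravel()).reshape(pts.shape)
        best = np.argmax(vals, axis=1)
        xs = pts[np.arange(len(xs)), best]
        fs = vals[np.arange(len(xs)), best]
        width /= 4.0
    near_top = fs >= fs.max() - 1e-9
    x_star = float(xs[near_top].min())
    return x_star, float(ws @ np.exp(-((cs - x_star) ** 2) / sigma))


def _denominator(mode: str, word_len: int, input_len: int, end_markers: bool) -> float:
    base = {
        "word": float(word_len),
        "input": float(input_len),
        "longer": float(max(word_len, input_len)),
        "shorter": float(min(word_len, input_len)),
        "mean": (word_len + input_len) / 2.0,
    }[mode]
    return base + (2.0 if end_markers else 0.0)


def match_value(
    name_a: CanonicalName,
    name_b: CanonicalName,
    params: MatchParams | None = None,
) -> MatchScore:
    """Match value of a name pair under one set of conventions.

    Encodes both names, binds letter tokens, superposes the Gaussian
    difference functions (marker channels contribute centers like letters),
    finds the peak, and divides by the comparison-letter count selected by
    ``params.denominator_mode``.  The result is in [0, 1] by construction:
    the peak never exceeds the number of centers, which never exceeds any
    of the selectable denominators.
    """
    params = params or MatchParams()
    if params.word_role == "first_name":
        word_name, input_name = name_a, name_b
    else:
        word_name, input_name = name_b, name_a
    word = encode(word_name, params.code_series)
    inp = encode(input_name, params.code_series)
    binding = bind_letters(
        word, inp, params.binding_mode, params.end_markers, params.exponent_scale
    )
    centers = binding.centers
    x_star, f_star = find_peak(centers, params.exponent_scale)
    l_i = _denominator(
        params.denominator_mode, word_name.length, input_name.length, params.end_markers
    )
    value = f_star / l_i
    profile = SuperpositionProfile(centers, params.exponent_scale, x_star, f_star)
    return MatchScore(value, l_i, params, profile, binding)


def grid_scores(
    name_a: CanonicalName,
    name_b: CanonicalName,
    grid: Iterable[MatchParams],
) -> dict[MatchParams, float]:
    """Match values for one pair under many conventions, sharing work.

    Encoding, binding and peak finding depend only on (word_role,
    code_series, binding_mode, end_markers, sigma); all denominator modes
    reuse the same peak.  Output values equal ``match_value`` one by one.
    """
    grid = list(grid)
    peak_cache: dict[tuple, float] = {}
    code_cache: dict[tuple[str, str], SpatialCode] = {}

    def code_of(name: CanonicalName, series: str) -> SpatialCode:
        key = (name.text, series)
        if key not in code_cache:
            code_cache[key] = encode(name, series)
        return code_cache[key]

    out: dict[MatchParams, float] = {}
    for p in grid:
        word_name, input_name = (
            (name_a, name_b) if p.word_role == "first_name" else (name_b, name_a)
        )
        key = (p.word_role, p.code_series, p.binding_mode, p.end_markers, p.exponent_scale)
        if key not in peak_cache:
            binding = bind_letters(
                code_of(word_name, p.code_series),
                code_of(input_name, p.code_series),
                p.binding_mode,
                p.end_markers,
                p.exponent_scale,
            )
            peak_cache[key] = find_peak(binding.centers, p.exponent_scale)[1]
        l_i = _denominator(p.denominator_mode, word_name.length, input_name.length, p.end_markers)
        out[p] = peak_cache[key] / l_i
    return out
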