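"""Secondary-structure parsing, pair-feature tensors, and loop classes.

Secondary structure arrives either as dot-bracket text (Vienna dialect,
with (), [], {}, <> bracket layers for pseudoknots) or as L x L base-pair
probability matrices.  Two sources are concatenated into the fixed
L x L x 4 pair-feature tensor consumed by the networks: two binary pair
maps followed by two probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_OPENERS = "([{<"
_CLOSERS = ")]}>"


class DotBracketError(ValueError):
    """Unbalanced or malformed dot-bracket input."""


@dataclass
class SecondaryStructure:
    """A set of base pairs plus optional pair-probability matrices."""

    pair_table: set = field(default_factory=set)
    probability_maps: list = field(default_factory=list)
    length: int = None

    def __post_init__(self):
        self.pair_table = {tuple(sorted(p)) for p in self.pair_table}
        for i, j in self.pair_table:
            if i == j:
                raise ValueError(f"residue {i} paired with itself")
        counts: dict[int, int] = {}
        for p in self.pair_table:
            for q in p:
                counts[q] = counts.get(q, 0) + 1
        multi = [q for q, c in counts.items() if c > 1]
        if multi:
            raise ValueError(f"residue(s) in more than one pair: {sorted(multi)}")
        if self.length is None:
            self.length = 1 + max((j for _, j in self.pair_table), default=-1)
        maps = []
        for m in self.probability_maps:
            m = np.asarray(m, dtype=float)
            if m.shape != (self.length, self.length):
                raise ValueError("probability map must be L x L")
            if m.min() < 0 or m.max() > 1:
                raise ValueError("probabilities must lie in [0, 1]")
            if np.abs(m - m.T).max() > 1e-9:
                raise ValueError("probability map must be symmetric")
            maps.append(m)
        self.probability_maps = maps

    def pair_matrix(self) -> np.ndarray:
        out = np.zeros((self.length, self.length))
        for i, j in self.pair_table:
            out[i, j] = out[j, i] = 1.0
        return out

    def partner(self) -> dict:
        out = {}
        for i, j in self.pair_table:
            out[i] = j
            out[j] = i
        return out


def parse_dot_bracket(text: str, probability_maps=()) -> SecondaryStructure:
    """Parse dot-bracket notation into a :class:`SecondaryStructure`.

    Each bracket family is an independent layer, so pseudoknots may be
    written with (), [], {}, <>.  Raises :class:`DotBracketError` with
    the offending position for unbalanced input.
    """
    text = text.strip()
    stacks: list[list[int]] = [[] for _ in _OPENERS]
    pairs = set()
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in _OPENERS:
            stacks[_OPENERS.index(ch)].append(pos)
        elif ch in _CLOSERS:
            layer = _CLOSERS.index(ch)
            if not stacks[layer]:
                raise DotBracketError(f"unmatched '{ch}' at position {pos}")
            pairs.add((stacks[layer].pop(), pos))
        else:
            raise DotBracketError(f"unexpected character {ch!r} at position {pos}")
    for layer, st in enumerate(stacks):
        if st:
            raise DotBracketError(
                f"unmatched '{_OPENERS[layer]}' at position {st[-1]}"
            )
    return SecondaryStructure(pairs, list(probability_maps), length=len(text))


def render_dot_bracket(ss: SecondaryStructure) -> str:
    """Inverse of :func:`parse_dot_bracket` for nested structures; deeper
    pseudoknot layers use successive bracket families."""
    out = ["."] * ss.length
    layers: list[list[tuple]] = []
    for p in sorted(ss.pair_table):
        for depth, layer in enumerate(layers):
            if all(not (a < p[0] < b < p[1] or p[0] < a < p[1] < b) for a, b in layer):
                layer.append(p)
                break
        else:
            depth = len(layers)
            layers.append([p])
        if depth >= len(_OPENERS):
            raise ValueError("more pseudoknot layers than bracket families")
        out[p[0]] = _OPENERS[depth]
        out[p[1]] = _CLOSERS[depth]
    return "".join(out)


def build_pair_features(
    ss_a: SecondaryStructure, ss_b: SecondaryStructure | None, L: int
) -> np.ndarray:
    """The L x L x 4 pair-feature tensor: binary pair maps of both
    sources (channels 0-1) and their probability maps (channels 2-3;
    zeros when a source carries none).  With a single source its
    channels are duplicated to keep the tensor shape fixed."""
    if ss_b is None:
        ss_b = ss_a
    for ss in (ss_a, ss_b):
        if ss.length != L:
            raise ValueError(f"secondary structure length {ss.length} != L={L}")
    out = np.zeros((L, L, 4))
    out[:, :, 0] = ss_a.pair_matrix()
    out[:, :, 1] = ss_b.pair_matrix()
    if ss_a.probability_maps:
        out[:, :, 2] = ss_a.probability_maps[0]
    if ss_b.probability_maps:
        out[:, :, 3] = ss_b.probability_maps[0]
    return out


def classify_loops(ss: SecondaryStructure, L: int) -> np.ndarray:
    """Boolean non-loop flag per residue: True iff base-paired."""
    if ss.length > L:
        raise ValueError("secondary structure longer than L")
    out = np.zeros(L, dtype=bool)
    for i, j in ss.pair_table:
        out[i] = out[j] = True
    return out
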