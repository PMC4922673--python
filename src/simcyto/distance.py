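"""Minimum-inversion distance between short banding sequences.

Parsimony on polytene maps asks for the fewest reversals carrying one band
order onto another.  At the handful-of-sections scale that cytological
derivations involve, breadth-first search over reversal space is exact and
fast: the state space is bounded by the number of distinct band orders, and
a visited set keeps the frontier small.  Comparison is unsigned (band order
only), matching what the maps record.
"""

from __future__ import annotations

from collections import deque

from .karyotype import ArmSequence, IncomparableSequenceError


class DepthExceededError(RuntimeError):
    """The search hit ``max_depth`` before connecting the two sequences."""


def _idents(seq) -> tuple:
    if isinstance(seq, ArmSequence):
        return seq.idents()
    return tuple(seq)


def _neighbours(state: tuple):
    n = len(state)
    for left in range(n - 1):
        for right in range(left + 2, n + 1):
            yield state[:left] + state[left:right][::-1] + state[right:]


def min_inversion_distance(a, b, max_depth: int = 10) -> int:
    """Length of the shortest reversal scenario transforming ``a`` into ``b``.

    Accepts :class:`~simcyto.karyotype.ArmSequence` objects or plain token
    tuples.  Raises :class:`DepthExceededError` when no scenario of length
    ``<= max_depth`` exists rather than returning a silent answer.
    """
    start, goal = _idents(a), _idents(b)
    if sorted(start) != sorted(goal):
        raise IncomparableSequenceError("sequences do not share a band-token multiset")
    if start == goal:
        return 0
    frontier = deque([(start, 0)])
    seen = {start}
    while frontier:
        state, depth = frontier.popleft()
        if depth >= max_depth:
            continue
        for nxt in _neighbours(state):
            if nxt == goal:
                return depth + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, depth + 1))
    raise DepthExceededError(f"no reversal scenario of length <= {max_depth} found")
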