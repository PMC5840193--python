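"""The (6,6) body-bar pebble game.

Rigidity of a molecular framework is decided combinatorially on a body-bar
multigraph: every atom is a rigid body with six degrees of freedom (six
pebbles), and every constraint contributes one or more bars between two
bodies.  A bar is *independent* -- it removes one degree of freedom -- if
and only if seven pebbles can be gathered on its two endpoints; the game
absorbs independent bars one by one, re-orienting previously absorbed bars
along augmenting paths.  By Tay's theorem the number of absorbed bars
equals the rank of the generic body-bar rigidity matrix, so the surviving
free pebbles count the framework's degrees of freedom (including the six
trivial rigid-body motions of each connected component).

Two queries on the finished game drive the analysis:

* :func:`collect_free_pebbles` -- the maximum number of free pebbles that
  can simultaneously be moved onto a chosen body subset.  Applied to the
  backbone bodies of a loop this is the loop's conformational DOF count
  (the six trivial pebbles included).
* :func:`rigid_clusters` -- the partition of bodies into maximal rigid
  clusters (two bodies are mutually rigid when no seventh pebble can be
  gathered on the pair).

The module is deliberately agnostic of chemistry: bodies are integers
``0..n-1`` and bars arrive as ``(u, v, bar_count)`` triples.  See
:mod:`abflex.network` for the construction of molecular constraint graphs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

__all__ = [
    "PebbleState",
    "play_pebble_game",
    "collect_free_pebbles",
    "rigid_clusters",
]

K = 6  # pebbles per body; a bar needs K + 1 pebbles on its endpoints


class PebbleState:
    """Directed multigraph state of a played body-bar pebble game.

    ``pebbles[v]`` is the number of free pebbles on body ``v``;
    ``out[v]`` maps successor bodies to the number of absorbed bars
    oriented away from ``v``.  The invariant ``pebbles[v] +
    sum(out[v].values()) == 6`` holds for every body.
    """

    __slots__ = ("n", "pebbles", "out", "redundant_bars", "_last_visited")

    def __init__(self, n_bodies: int):
        if n_bodies < 1:
            raise ValueError("pebble game needs at least one body")
        self.n = n_bodies
        self.pebbles = [K] * n_bodies
        self.out: list[dict[int, int]] = [{} for _ in range(n_bodies)]
        self.redundant_bars = 0

    # -- elementary moves ---------------------------------------------------

    def _find_and_pull(self, src: int, blocked: frozenset[int] | set[int]) -> bool:
        """Pull one free pebble to ``src`` along an augmenting path.

        Follows absorbed-bar orientations from ``src``; a free pebble found
        on a body outside ``blocked`` is moved back to ``src`` by reversing
        every bar on the path.  Returns False when no such pebble is
        reachable (the search's visited set is then pebble-free and closed
        under reachability, a fact :func:`rigid_clusters` exploits).
        """
        pebbles = self.pebbles
        out = self.out
        parent: dict[int, int | None] = {src: None}
        stack = [src]
        found = -1
        while stack:
            x = stack.pop()
            for y in out[x]:
                if y in parent:
                    continue
                parent[y] = x
                if pebbles[y] > 0 and y not in blocked:
                    found = y
                    stack.clear()
                    break
                stack.append(y)
        if found < 0:
            self._last_visited = parent  # type: ignore[attr-defined]
            return False
        # reverse the path found -> ... -> src
        cur = found
        while True:
            p = parent[cur]
            if p is None:
                break
            cnt = out[p][cur] - 1
            if cnt:
                out[p][cur] = cnt
            else:
                del out[p][cur]
            out[cur][p] = out[cur].get(p, 0) + 1
            cur = p
        pebbles[found] -= 1
        pebbles[src] += 1
        return True

    def _gather_pair(self, u: int, v: int) -> bool:
        """Try to gather K+1 pebbles on ``{u, v}``; True on success."""
        blocked = {u, v}
        while self.pebbles[u] + self.pebbles[v] <= K:
            if self._find_and_pull(u, blocked):
                continue
            if self._find_and_pull(v, blocked):
                continue
            return False
        return True

    def add_bars(self, u: int, v: int, bars: int) -> int:
        """Process ``bars`` parallel bars between ``u`` and ``v``.

        Each bar is absorbed if independent, otherwise counted redundant.
        Returns the number absorbed.  Supports incremental use: bars may be
        added after earlier queries, which is what the hydrogen-bond
        dilution sweep relies on.
        """
        if u == v:
            raise ValueError("self-loops carry no rigidity information")
        if not (0 <= u < self.n and 0 <= v < self.n):
            raise ValueError(f"bar ({u},{v}) references unknown bodies (n={self.n})")
        absorbed = 0
        for _ in range(bars):
            if self._gather_pair(u, v):
                # total >= K+1 and each body holds <= K, so pebbles[u] >= 1
                self.pebbles[u] -= 1
                self.out[u][v] = self.out[u].get(v, 0) + 1
                absorbed += 1
            else:
                self.redundant_bars += 1
        return absorbed

    # -- queries ------------------------------------------------------------

    @property
    def total_free_pebbles(self) -> int:
        return sum(self.pebbles)

    def copy(self) -> "PebbleState":
        dup = PebbleState.__new__(PebbleState)
        dup.n = self.n
        dup.pebbles = list(self.pebbles)
        dup.out = [dict(d) for d in self.out]
        dup.redundant_bars = self.redundant_bars
        return dup


def play_pebble_game(
    n_bodies: int,
    edges: Iterable[tuple[int, int, int]],
) -> PebbleState:
    """Run the (6,6) pebble game over an edge multiset.

    ``edges`` yields ``(u, v, bar_count)`` triples; the result is
    independent of their order (the absorbed-bar count is the rank of a
    matroid), although the orientation details are not.
    """
    state = PebbleState(n_bodies)
    for u, v, bars in edges:
        state.add_bars(u, v, bars)
    return state


def collect_free_pebbles(state: PebbleState, target_bodies: Sequence[int]) -> int:
    """Maximum free pebbles simultaneously placeable on ``target_bodies``.

    This is the degree-of-freedom count of the sub-framework spanned by the
    targets, the six trivial rigid-body pebbles included.  The query runs
    on a copy, leaving ``state`` untouched.
    """
    targets = list(dict.fromkeys(target_bodies))
    if not targets:
        raise ValueError("empty target set")
    work = state.copy()
    frozen = set(targets)
    for t in targets:
        while work.pebbles[t] < K:
            if not work._find_and_pull(t, frozen):
                break
    return sum(work.pebbles[t] for t in targets)


def rigid_clusters(state: PebbleState) -> list[set[int]]:
    """Partition bodies into maximal rigid clusters.

    Two bodies are in one cluster when at most six pebbles can be gathered
    on the pair, i.e. they admit no relative motion.  Implemented with the
    standard failed-search expansion: pin six pebbles on a seed body, then
    every body from which no free pebble is reachable (seed excluded) is
    rigid with the seed -- and so is the whole pebble-free visited set of
    that failed search, assigning many bodies per search.
    """
    labels = [-1] * state.n
    clusters: list[set[int]] = []
    for u in range(state.n):
        if labels[u] != -1:
            continue
        work = state.copy()
        while work.pebbles[u] < K:
            if not work._find_and_pull(u, set()):  # pragma: no cover - always succeeds
                raise AssertionError("a single body always retains its 6 trivial pebbles")
        cid = len(clusters)
        members = {u}
        labels[u] = cid
        for v in range(state.n):
            if labels[v] != -1 or v == u:
                continue
            if work.pebbles[v] > 0:
                continue
            if not work._find_and_pull(v, {u}):
                visited = work._last_visited  # type: ignore[attr-defined]
                for w in visited:
                    if w != u and work.pebbles[w] == 0 and labels[w] == -1:
                        labels[w] = cid
                        members.add(w)
                labels[v] = cid
                members.add(v)
        clusters.append(members)
    return clusters
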