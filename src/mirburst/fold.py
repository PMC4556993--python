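"""Hairpin secondary-structure prediction and folding-stability null models.

The folding engine is a weighted Nussinov dynamic program: it returns the
nested (pseudoknot-free) structure minimising the sum of base-pair weights
GC = -3.0, AU = -2.0, GU = -1.0 kcal/mol-equivalent, with a minimum hairpin
loop of 3 unpaired bases.  This is a deliberately simple, fully specified
energy model — adequate for ranking hairpin candidates and for shuffle-based
significance testing, not for reproducing thermodynamic free energies.

Folding significance is assessed against dinucleotide-shuffled controls
(Altschul–Erickson Eulerian-walk shuffling), which preserve both mono- and
dinucleotide composition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SecondaryStructure",
    "fold_mfe",
    "is_hairpin",
    "dinucleotide_shuffle",
    "mfe_z",
    "PAIR_WEIGHTS",
    "MIN_LOOP",
]

#: pair weights in kcal/mol-equivalents (negative = stabilising)
PAIR_WEIGHTS = {("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0}
#: minimum number of unpaired bases enclosed by a pair
MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# weight matrix indexed by the base codes above; symmetric
_W = np.zeros((4, 4), dtype=np.float64)
for (_a, _b), _w in PAIR_WEIGHTS.items():
    _W[_CODE[_a], _CODE[_b]] = _w
    _W[_CODE[_b], _CODE[_a]] = _w


@dataclass
class SecondaryStructure:
    """A nested secondary structure for one sequence.

    ``pairs`` are 0-based ``(i, j)`` with ``i < j``; ``energy`` is the sum of
    pair weights (<= 0); ``dotbracket`` is the usual '(', ')', '.' string.
    """

    sequence: str
    pairs: list[tuple[int, int]] = field(default_factory=list)
    energy: float = 0.0

    @property
    def dotbracket(self) -> str:
        db = ["."] * len(self.sequence)
        for i, j in self.pairs:
            db[i] = "("
            db[j] = ")"
        return "".join(db)

    def partner_map(self) -> dict[int, int]:
        """Map each paired index to its partner (both directions)."""
        pm: dict[int, int] = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    @property
    def paired_fraction(self) -> float:
        n = len(self.sequence)
        return 2.0 * len(self.pairs) / n if n else 0.0


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc.args[0]!r} in sequence")


@njit(cache=True)
def _nussinov_table(code, W):  # pragma: no cover - exercised via fold_mfe
    n = code.shape[0]
    E = np.zeros((n, n), dtype=np.float64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                w = W[code[i], code[k]]
                if w < 0.0:
                    cand = w
                    if k - 1 > i + 1:
                        cand += E[i + 1, k - 1]
                    if k + 1 <= j - 1:
                        cand += E[k + 1, j]
                    if cand < best:
                        best = cand
            E[i, j] = best
    return E


def _traceback(code: np.ndarray, E: np.ndarray) -> list[tuple[int, int]]:
    # Mirrors the DP's choice rule: at equal energy prefer pairing i with the
    # smallest admissible k over leaving i unpaired.
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(code) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        target = E[i, j]
        chosen = None
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = _W[code[i], code[k]]
            if w >= 0.0:
                continue
            cand = w
            if k - 1 > i + 1:
                cand += E[i + 1, k - 1]
            if k + 1 <= j - 1:
                cand += E[k + 1, j]
            if cand == target:
                chosen = k
                break
        if chosen is not None:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    return sorted(pairs)


def fold_mfe(seq: str) -> SecondaryStructure:
    """Fold ``seq`` (DNA or RNA alphabet; T read as U) to its minimum-energy
    nested structure under the package's pair-weight model.

    Deterministic tie-break: pairing the 5'-most free base beats leaving it
    unpaired, and among equal-energy partners the 5'-most partner wins.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    code = _encode(seq)
    if len(code) < MIN_LOOP + 2:
        return SecondaryStructure(seq, [], 0.0)
    E = _nussinov_table(code, _W)
    pairs = _traceback(code, E)
    return SecondaryStructure(seq, pairs, float(E[0, len(code) - 1]))


def is_hairpin(struct: SecondaryStructure) -> tuple[bool, int, float]:
    """Test whether a structure is a single stem-loop.

    Returns ``(flag, longest_helix_run, paired_fraction)``.  The flag is true
    iff the pairs, sorted by their 5' index, have strictly decreasing 3'
    indices — a single ladder with bulges and internal loops allowed, but no
    multi-loop (two sibling stems anywhere).  Structures with no pairs are
    not hairpins.
    """
    pairs = sorted(struct.pairs)
    if not pairs:
        return False, 0, 0.0
    flag = all(pairs[k][1] > pairs[k + 1][1] for k in range(len(pairs) - 1))
    # longest run of directly stacked pairs (i+1, j-1)
    run = best = 1
    for k in range(len(pairs) - 1):
        i0, j0 = pairs[k]
        i1, j1 = pairs[k + 1]
        if i1 == i0 + 1 and j1 == j0 - 1:
            run += 1
            best = max(best, run)
        else:
            run = 1
    return flag, best, struct.paired_fraction


def ladders(struct: SecondaryStructure) -> list[list[tuple[int, int]]]:
    """Split pairs (sorted by 5' index) into maximal decreasing-3' runs.

    Each run approximates one stem-loop; a clean hairpin yields one run.
    """
    pairs = sorted(struct.pairs)
    runs: list[list[tuple[int, int]]] = []
    for p in pairs:
        if runs and p[1] < runs[-1][-1][1]:
            runs[-1].append(p)
        else:
            runs.append([p])
    return runs


def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator = 0) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide (and hence
    mononucleotide) composition, by the Altschul–Erickson Eulerian-walk
    construction.  The first and last characters are preserved.
    """
    if len(seq) < 3:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = seq.upper()
    last = s[-1]
    # successor edge lists per vertex (character)
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges.keys())
    for v in set(s) - set(vertices):
        vertices.append(v)

    def connected_to_last(last_edge: dict[str, str]) -> bool:
        # every vertex with out-edges must reach `last` via chosen last edges
        for v in edges:
            if v == last:
                continue
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in last_edge:
                    return False
                seen.add(u)
                u = last_edge[u]
        return True

    # choose a random last edge per vertex (except the terminal one) until the
    # last-edge graph is connected to the terminal vertex
    while True:
        last_edge = {
            v: lst[rng.integers(len(lst))] for v, lst in edges.items() if v != last
        }
        if connected_to_last(last_edge):
            break

    shuffled_lists: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v != last:
            rest.remove(last_edge[v])
        order = rng.permutation(len(rest))
        rest = [rest[k] for k in order]
        if v != last:
            rest.append(last_edge[v])
        shuffled_lists[v] = rest

    out = [s[0]]
    pos = {v: 0 for v in shuffled_lists}
    u = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled_lists[u][pos[u]]
        pos[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def mfe_z(
    seq: str,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Folding-stability z-score against dinucleotide-shuffled controls.

    ``z = (E_seq - mean(E_shuffled)) / sd(E_shuffled)``; returns 0.0 when the
    shuffled energies are constant.  Strongly negative z means the sequence
    folds better than its composition alone explains.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e0 = fold_mfe(seq).energy
    es = np.array(
        [fold_mfe(dinucleotide_shuffle(seq, rng)).energy for _ in range(n_shuffles)]
    )
    sd = float(es.std(ddof=1))
    if sd == 0.0:
        return 0.0
    return float((e0 - es.mean()) / sd)
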