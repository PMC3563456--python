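"""RNA hairpin folding by maximum-weight nested base pairing.

A Nussinov-style dynamic program finds the highest-weight pseudoknot-free
pairing under a simple per-pair weight scheme (default GC=3, AU=2, GU=1,
minimum hairpin loop of 3 unpaired nt). This favours long, GC-rich stems —
the property that distinguishes pre-miRNA-like introns from unstructured
ones — while staying exactly checkable against exhaustive enumeration.
Traceback tie-breaking is fully deterministic (pair the leftmost base
whenever pairing attains the optimum, with its smallest admissible partner),
so identical inputs give bit-identical structures.

An external thermodynamic folder can be plugged in for cross-checks via
``fold_hairpin(..., folder=callable)``; nothing in the package requires one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

DEFAULT_WEIGHTS: Dict[str, int] = {"GC": 3, "AU": 2, "GU": 1}

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class HairpinStructure:
    """A folded sequence: dot-bracket string, 1-based pair list, total weight."""

    sequence: str
    dotbracket: str
    pairs: Tuple[Tuple[int, int], ...]
    score: float


@dataclass(frozen=True)
class HairpinFeatures:
    """Structural features of the main stem-loop, feeding the mirtron score.

    stem_len counts base pairs along the main stem path (outermost pair to
    the terminal loop); n_bulges counts interruptions of that path;
    overhangs are unpaired nt outside the outermost pair.
    """

    stem_len: int
    loop_len: int
    paired_fraction: float
    overhang5: int
    overhang3: int
    n_bulges: int
    gu_fraction: float


def _weight_matrix(weights: Dict[str, int]) -> np.ndarray:
    w = np.zeros((4, 4), dtype=np.int64)
    for pair, val in weights.items():
        a, b = _CODE[pair[0]], _CODE[pair[1]]
        w[a, b] = val
        w[b, a] = val
    return w


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA character {exc.args[0]!r}") from None


@njit(cache=True)
def _nussinov_table(codes, min_loop, wmat):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    W = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                w = wmat[codes[i], codes[k]]
                if w > 0:
                    s = w + W[i + 1, k - 1] + W[k + 1, j]
                    if s > best:
                        best = s
            W[i, j] = best
    return W


def _traceback(
    codes: np.ndarray, W: np.ndarray, min_loop: int, wmat: np.ndarray
) -> List[Tuple[int, int]]:
    pairs: List[Tuple[int, int]] = []
    stack = [(0, codes.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = W[i, j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            w = wmat[codes[i], codes[k]]
            if w > 0 and w + W[i + 1, k - 1] + W[k + 1, j] == target:
                pairs.append((i + 1, k + 1))  # 1-based
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    pairs.sort()
    return pairs


def pairs_to_dotbracket(pairs: List[Tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i - 1] = "("
        db[j - 1] = ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> Tuple[Tuple[int, int], ...]:
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for pos, c in enumerate(db, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), pos))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


def fold_hairpin(
    sequence: str,
    min_loop: int = 3,
    weights: Optional[Dict[str, int]] = None,
    folder: Optional[Callable[[str], str]] = None,
) -> HairpinStructure:
    """Fold an RNA sequence into its maximum-weight nested pairing.

    ``sequence`` must be over {A,C,G,U} (T is accepted and converted);
    sequences containing N are rejected and should be excluded upstream.
    An optional ``folder`` callable (sequence -> dot-bracket) substitutes an
    external structure prediction; the pair list is then re-scored under the
    same weight scheme.
    """
    seq = sequence.upper().replace("T", "U")
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    if len(seq) < min_loop + 2:
        raise ValueError(f"sequence length {len(seq)} < min_loop + 2")
    codes = _encode(seq)
    wmat = _weight_matrix(weights)
    if folder is not None:
        db = folder(seq)
        pairs = dotbracket_to_pairs(db)
        score = sum(wmat[codes[i - 1], codes[j - 1]] for i, j in pairs)
        return HairpinStructure(seq, db, pairs, float(score))
    W = _nussinov_table(codes, min_loop, wmat)
    pairs = _traceback(codes, W, min_loop, wmat)
    return HairpinStructure(
        seq, pairs_to_dotbracket(pairs, len(seq)), tuple(pairs), float(W[0, len(seq) - 1])
    )


def brute_force_fold(
    sequence: str, min_loop: int = 3, weights: Optional[Dict[str, int]] = None
) -> float:
    """Best score over an explicit enumeration of all nested pairings.

    Independent oracle for the dynamic program; guarded to length <= 14
    because the enumeration is combinatorial.
    """
    seq = sequence.upper().replace("T", "U")
    if len(seq) > 14:
        raise ValueError("brute_force_fold is limited to length <= 14")
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    wmat = _weight_matrix(weights)
    codes = _encode(seq)

    def structures(positions: Tuple[int, ...]):
        """Yield every nested pairing over the given (sorted) positions."""
        if not positions:
            yield ()
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for s in structures(rest):
            yield s
        # first paired with a later position: nesting forces a split
        for idx, k in enumerate(rest):
            if k - first <= min_loop:
                continue
            if wmat[codes[first], codes[k]] <= 0:
                continue
            inside = tuple(p for p in rest[:idx])
            outside = tuple(p for p in rest[idx + 1 :])
            for s_in in structures(inside):
                for s_out in structures(outside):
                    yield ((first, k),) + s_in + s_out

    best = 0.0
    for struct in structures(tuple(range(len(seq)))):
        score = float(sum(wmat[codes[i], codes[j]] for i, j in struct))
        if score > best:
            best = score
    return best


def main_stem_path(pairs: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Pairs along the main stem, outermost to innermost.

    Descends from the virtual root into the child branch carrying the most
    pairs (leftmost on ties) until the terminal loop. Empty for a pairless
    structure.
    """
    pairs = sorted(pairs)
    if not pairs:
        return []
    children: Dict[Optional[Tuple[int, int]], List[Tuple[int, int]]] = {None: []}
    stack: List[Tuple[int, int]] = []
    for pair in pairs:  # pairs sorted by i; nesting via a stack
        while stack and pair[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(pair)
        children.setdefault(pair, [])
        stack.append(pair)

    def subtree_size(p: Tuple[int, int]) -> int:
        return 1 + sum(subtree_size(c) for c in children[p])

    path: List[Tuple[int, int]] = []
    node: Optional[Tuple[int, int]] = None
    while children[node]:
        node = max(children[node], key=lambda c: (subtree_size(c), -c[0]))
        path.append(node)
    return path


def extract_features(structure: HairpinStructure) -> HairpinFeatures:
    """Compute stem/loop/overhang/bulge features from the pair list.

    The main stem path descends from the outermost pair into the child
    branch carrying the most pairs (leftmost on ties) until the terminal
    loop. A pairless structure reports zero stem and the sequence length
    split at the midpoint as overhangs.
    """
    n = len(structure.sequence)
    pairs = list(structure.pairs)
    if not pairs:
        return HairpinFeatures(0, 0, 0.0, n // 2, n - n // 2, 0, 0.0)

    paired_fraction = 2 * len(pairs) / n
    gu = sum(
        1
        for i, j in pairs
        if {structure.sequence[i - 1], structure.sequence[j - 1]} == {"G", "U"}
    )
    gu_fraction = gu / len(pairs)
    overhang5 = min(i for i, _ in pairs) - 1
    overhang3 = n - max(j for _, j in pairs)

    path = main_stem_path(pairs)
    stem_len = len(path)
    inner = path[-1]
    loop_len = inner[1] - inner[0] - 1
    n_bulges = 0
    for (i1, j1), (i2, j2) in zip(path, path[1:]):
        if (i2 - i1 - 1) + (j1 - j2 - 1) > 0:
            n_bulges += 1
    return HairpinFeatures(
        stem_len, loop_len, paired_fraction, overhang5, overhang3, n_bulges, gu_fraction
    )


def write_vienna(structure: HairpinStructure, path) -> None:
    """Write sequence + dot-bracket in plain two-line Vienna text layout."""
    with open(path, "w") as fh:
        fh.write(f"{structure.sequence}\n{structure.dotbracket}\n")
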