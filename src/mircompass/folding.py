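"""RNA secondary-structure prediction by maximum base pairing.

Hairpin screening here needs duplex *geometry* — which mature bases pair,
where the terminal loop sits — not free energies, so the backend is a
Nussinov-style dynamic program maximising the number of base pairs
(Watson-Crick plus G·U wobble) subject to a minimum hairpin-loop size.
The traceback is deterministic: at a tie the pair (i, j) closing the
current interval is preferred over leaving i unpaired or bifurcating, and
among bifurcations the 5'-most partner wins, resolved outermost-first.
The backend is intentionally pluggable: any function returning a balanced
dot-bracket string can stand in for :func:`fold`.
"""

from __future__ import annotations

import numpy as np

from ._seq import encode

try:  # pragma: no cover - exercised implicitly by every fold call
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: allowed pairs on encoded bases (A=0, C=1, G=2, U/T=3): WC + G.U wobble
_PAIRABLE = np.zeros((5, 5), dtype=np.bool_)
for a, b in [(0, 3), (1, 2), (2, 3)]:  # A-U, C-G, G-U
    _PAIRABLE[a, b] = True
    _PAIRABLE[b, a] = True


def _fill_py(codes: np.ndarray, min_loop: int) -> np.ndarray:
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int16)
    for length in range(min_loop + 1, n):
        for i in range(n - length):
            j = i + length
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if _PAIRABLE[codes[i], codes[k]]:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    cand = inner + 1 + right
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


if _HAVE_NUMBA:
    _fill_jit = njit(cache=True)(_fill_py)


def _fill(codes: np.ndarray, min_loop: int) -> np.ndarray:
    if _HAVE_NUMBA:
        return _fill_jit(codes, min_loop)
    return _fill_py(codes, min_loop)


def fold(rna: str, min_loop: int = 3) -> tuple[str, int]:
    """Fold an RNA (or DNA) string; return (dot-bracket, number of pairs).

    Parameters
    ----------
    rna:
        Sequence over {A, C, G, U/T, N}; N pairs with nothing.
    min_loop:
        Minimum number of unpaired bases enclosed by any pair (hairpin
        loop size), default 3.

    The result is deterministic for a given input.
    """
    n = len(rna)
    if n < min_loop + 2:
        raise ValueError(f"sequence of length {n} cannot close a loop of {min_loop}")
    codes = encode(rna)
    dp = _fill(codes, min_loop)

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        # prefer pairing i (with j first, then the 5'-most valid partner)
        paired = False
        if _PAIRABLE[codes[i], codes[j]] and j - i - 1 >= min_loop:
            inner = dp[i + 1, j - 1] if j - 1 >= i + 1 else 0
            if dp[i, j] == inner + 1:
                structure[i], structure[j] = "(", ")"
                stack.append((i + 1, j - 1))
                paired = True
        if not paired:
            if dp[i, j] == dp[i + 1, j]:
                stack.append((i + 1, j))
            else:
                for k in range(i + min_loop + 1, j + 1):
                    if not _PAIRABLE[codes[i], codes[k]]:
                        continue
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    if dp[i, j] == inner + 1 + right:
                        structure[i], structure[k] = "(", ")"
                        stack.append((i + 1, k - 1))
                        stack.append((k + 1, j))
                        paired = True
                        break
                if not paired:  # pragma: no cover - DP guarantees a branch
                    raise AssertionError("traceback failed")
    return "".join(structure), int(dp[0, n - 1])


def pair_table(dotbracket: str) -> np.ndarray:
    """Partner index per position (-1 if unpaired) from a dot-bracket string.

    Raises ``ValueError`` on unbalanced input.
    """
    partners = np.full(len(dotbracket), -1, dtype=np.int64)
    stack: list[int] = []
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            op = stack.pop()
            partners[op] = idx
            partners[idx] = op
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} in dot-bracket string")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partners
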