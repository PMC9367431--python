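"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration rather than
calling back into the package's optimised code paths.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from genomesurvey.ssr import minimal_period

BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def brute_force_ssrs(
    seq: str, min_repeats: Dict[int, int]
) -> List[Tuple[int, int, int, str, int]]:
    """Exhaustive SSR enumeration: try every start and period, extend by
    whole motif copies, keep left-maximal runs above threshold with
    minimal-period motifs, then apply the longest-span-wins overlap rule.

    Returns sorted (start0, end0, period, motif, repeats) tuples.
    """
    n = len(seq)
    cands = set()
    for i in range(n):
        for p in range(2, 7):
            motif = seq[i : i + p]
            if len(motif) < p or "N" in motif:
                continue
            if minimal_period(motif) != p:
                continue
            # left-maximal: the run must not extend one base to the left
            if i > 0 and seq[i - 1] != "N" and seq[i - 1] == seq[i - 1 + p]:
                continue
            reps = 0
            j = i
            while seq[j : j + p] == motif:
                reps += 1
                j += p
            if reps >= min_repeats[p]:
                cands.add((p * reps, p, i, i + p * reps - 1, motif))
    ordered = sorted(cands, key=lambda c: (-c[0], c[1], c[2]))
    accepted: List[Tuple[int, int, int, str, int]] = []
    for span, p, s, e, motif in ordered:
        if any(s <= ae and e >= as_ for as_, ae, *_ in accepted):
            continue
        accepted.append((s, e, p, motif, span // p))
    return sorted(accepted)


def brute_force_nxx(lengths: List[int], x: float) -> int:
    """Nxx by direct scan of the descending-sorted lengths."""
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= x / 100.0 * total:
            return L
    raise AssertionError("unreachable for x <= 100")


def random_ssr_rich_sequence(rng: np.random.Generator, length: int = 500) -> str:
    """Random test sequence; alternates between uniform ACGT(N), two-letter
    alphabets (tandem-rich) and uniform-with-planted-motif-runs, to
    exercise thresholds and overlap resolution."""
    mode = rng.integers(0, 3)
    if mode == 0:
        arr = rng.choice(5, size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04])
        return BASES[arr].tobytes().decode()
    if mode == 1:
        alphabet = rng.choice(4, size=2, replace=False)
        return BASES[rng.choice(alphabet, size=length)].tobytes().decode()
    arr = rng.integers(0, 4, size=length)
    seq = BASES[arr].tobytes().decode()
    out = []
    pos = 0
    while pos < length:
        out.append(seq[pos : pos + 40])
        pos += 40
        p = int(rng.integers(1, 7))
        motif = BASES[rng.integers(0, 4, size=p)].tobytes().decode()
        out.append(motif * int(rng.integers(2, 9)))
    return "".join(out)[:length]
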