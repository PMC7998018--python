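"""Independent brute-force oracles used only by the tests.

Deliberately naive and coded without reusing any package internals, so
they can serve as ground truth for the efficient implementations.
"""

from __future__ import annotations


def literal_correction(values, k: int = 6, max_passes: int = 50):
    """Naive interpreter of the noisy-segment correction procedure.

    Scans the raw list for maximal equal-value segments from scratch on
    every step; for i = 1..k flips the leftmost interior segment of
    length exactly i whose flank lengths satisfy
    (j_left >= i and j_right >= i+1) or (j_right >= i and j_left >= i+1),
    restarting the scan after each flip; repeats the whole sweep until
    nothing changes.
    """
    s = [int(v) for v in values]
    for _ in range(max_passes):
        snapshot = list(s)
        for i in range(1, k + 1):
            while True:
                # segment boundaries [start, stop) of equal values
                segs = []
                start = 0
                for j in range(1, len(s) + 1):
                    if j == len(s) or s[j] != s[start]:
                        segs.append((start, j))
                        start = j
                hit = False
                for idx in range(1, len(segs) - 1):
                    a, b = segs[idx]
                    if b - a != i:
                        continue
                    j_left = segs[idx - 1][1] - segs[idx - 1][0]
                    j_right = segs[idx + 1][1] - segs[idx + 1][0]
                    if (j_left >= i and j_right >= i + 1) or (j_right >= i and j_left >= i + 1):
                        for t in range(a, b):
                            s[t] = 1 - s[t]
                        hit = True
                        break
                if not hit:
                    break
        if s == snapshot:
            return s
    raise RuntimeError("oracle did not converge")


def pair_counting_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic: the fraction of
    positive/negative pairs ranked correctly, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
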