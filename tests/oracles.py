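"""Brute-force reference implementations used only to check the package.

These deliberately use the slowest, most literal formulation of each rule so
they share no code path with the library.
"""

from __future__ import annotations

import numpy as np


def ttc_bruteforce(jumps) -> tuple[int, bool, bool]:
    """Scan every trial for the first jump followed by >= 5 no-jump trials."""
    jumps = list(int(j) for j in jumps)
    n = len(jumps)
    jumper = any(jumps[:5])
    for t in range(n):  # 0-based candidate jump trial
        if jumps[t] != 1:
            continue
        window = jumps[t + 1 : t + 6]
        if len(window) == 5 and sum(window) == 0:
            return t + 1, False, jumper
    return n, True, jumper


def sleep_bouts_rle(counts, bin_seconds: int = 30, threshold_min: float = 5.0):
    """Run-length encode zero-count runs, keep runs of >= threshold minutes.

    Returns (sleep boolean list, [(start_bin, n_bins), ...]).
    """
    counts = list(counts)
    runs = []
    i = 0
    while i < len(counts):
        if counts[i] == 0:
            j = i
            while j < len(counts) and counts[j] == 0:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    min_bins = int(round(threshold_min * 60 / bin_seconds))
    bouts = [(s, ln) for s, ln in runs if ln >= min_bins]
    sleep = [False] * len(counts)
    for s, ln in bouts:
        for b in range(s, s + ln):
            sleep[b] = True
    return sleep, bouts


def delta_ct_bruteforce(rows, target, refs):
    """Cell-by-cell ddCT recomputation from a list of row dicts."""
    out = {}
    cells = {(r["tissue"], r["stage"], r["replicate"]) for r in rows if r["gene"] == target}
    for cell in cells:
        tissue, stage, rep = cell
        tgt = [r["ct"] for r in rows
               if r["gene"] == target and (r["tissue"], r["stage"], r["replicate"]) == cell]
        ref = [r["ct"] for r in rows
               if r["gene"] in refs and (r["tissue"], r["stage"], r["replicate"]) == cell]
        dct = np.mean(tgt) - np.mean(ref)
        out[cell] = (dct, 2.0 ** (-dct))
    return out
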