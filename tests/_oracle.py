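"""Independent brute-force oracles used only by tests.

These deliberately share no code with the package: the decomposition oracle
enumerates every admissible (shift, trim, extension, tail, substitutions)
explanation of a read and minimizes the edit count directly, and the BH
oracle applies the step-up formula literally.
"""

from __future__ import annotations

from typing import Optional

import numpy as np


def enumerate_decompositions(seq, hairpin_seq, mat_start, mat_end, params, mature_id):
    """Yield every admissible decomposition as a dict, with no greediness."""
    mat_len = mat_end - mat_start
    core_lo = params.core_start
    core_hi = min(params.core_end, mat_len)
    for shift5 in range(-params.max_5p_shift, params.max_5p_shift + 1):
        s = mat_start + shift5
        if s < 0:
            continue
        read_end = s + len(seq)
        if read_end <= mat_end:
            combos = [(mat_end - read_end, 0, 0)]  # (trim3, ext3, tail_len)
        else:
            overhang = read_end - mat_end
            combos = [
                (0, ext3, overhang - ext3)
                for ext3 in range(0, overhang + 1)
            ]
            if params.allow_trim_tail:
                for tail_len in range(1, len(seq)):
                    trim3 = mat_end - (s + len(seq) - tail_len)
                    if trim3 > 0:
                        combos.append((trim3, 0, tail_len))
        for trim3, ext3, tail_len in combos:
            if trim3 > params.max_3p_trim or ext3 > params.max_3p_ext:
                continue
            if tail_len > params.max_3p_ext:
                continue
            body_len = len(seq) - tail_len - ext3 if (ext3 or tail_len) else len(seq)
            body_len = len(seq) - tail_len - ext3
            if body_len < 0 or s + body_len + ext3 > len(hairpin_seq):
                continue
            # templated extension must match the hairpin exactly
            ext_seq = seq[body_len : body_len + ext3]
            if ext_seq != hairpin_seq[mat_end : mat_end + ext3]:
                continue
            # the body must end exactly at mat_end - trim3
            if s + body_len != mat_end - trim3:
                continue
            subs = []
            ok = True
            for i in range(body_len):
                if seq[i] != hairpin_seq[s + i]:
                    mat_pos = s + i - mat_start
                    if core_lo <= mat_pos < core_hi:
                        ok = False
                        break
                    subs.append((i, hairpin_seq[s + i], seq[i]))
            if not ok or len(subs) > params.max_mismatch:
                continue
            tail = seq[len(seq) - tail_len :] if tail_len else ""
            edits = abs(shift5) + trim3 + ext3 + tail_len + len(subs)
            yield {
                "mature_id": mature_id,
                "shift5": shift5,
                "trim3": trim3,
                "ext3": ext3,
                "tail": tail,
                "substitutions": tuple(subs),
                "edits": edits,
            }


def brute_force_decompose(seq, hairpin_seq, mat_start, mat_end, params, mature_id="m"):
    """Minimum-edit decomposition under the (edits, |shift5|, |tail|) tie-break."""
    best: Optional[dict] = None
    for cand in enumerate_decompositions(
        seq, hairpin_seq, mat_start, mat_end, params, mature_id
    ):
        key = (cand["edits"], abs(cand["shift5"]), len(cand["tail"]), cand["mature_id"])
        if best is None or key < (
            best["edits"],
            abs(best["shift5"]),
            len(best["tail"]),
            best["mature_id"],
        ):
            best = cand
    return best


def bh_step_up(pvalues):
    """Literal Benjamini–Hochberg step-up: sort, scale by n/i, monotonize."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = ranked * n / np.arange(1, n + 1)
    # enforce monotone non-decreasing from the largest rank down
    for i in range(n - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    scaled = np.minimum(scaled, 1.0)
    out = np.empty(n)
    out[order] = scaled
    return out.tolist()


def random_read_pair(rng, params):
    """A random (hairpin, mature interval, read) triple for oracle testing.

    Mixes reads derived from the mature by random edits with fully random
    sequences, over hairpins up to 60 nt.
    """
    bases = np.array(list("ACGU"))
    hp_len = int(rng.integers(30, 61))
    hairpin = "".join(rng.choice(bases, size=hp_len))
    mat_len = int(rng.integers(15, min(27, hp_len - 4)))
    start = int(rng.integers(0, hp_len - mat_len + 1))
    end = start + mat_len
    mature = hairpin[start:end]

    if rng.random() < 0.25:
        read_len = int(rng.integers(15, 31))
        read = "".join(rng.choice(bases, size=read_len))
    else:
        read = mature
        shift = int(rng.integers(-params.max_5p_shift, params.max_5p_shift + 1))
        s = start + shift
        if 0 <= s and s < end:
            read = hairpin[s:end]
        op = rng.random()
        if op < 0.3:  # 3' trim
            k = int(rng.integers(1, params.max_3p_trim + 1))
            read = read[:-k] if len(read) - k >= 1 else read
        elif op < 0.55:  # 3' extension / tail
            k = int(rng.integers(1, params.max_3p_ext + 1))
            read = read + "".join(rng.choice(bases, size=k))
        elif op < 0.75:  # substitution
            if len(read) > 1:
                pos = int(rng.integers(0, len(read)))
                alt = str(rng.choice([b for b in "ACGU" if b != read[pos]]))
                read = read[:pos] + alt + read[pos + 1 :]
    if not (15 <= len(read) <= 30):
        read = (read + mature)[:22]
    return hairpin, start, end, read
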