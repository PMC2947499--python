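"""Exhaustive bisulfite-aware alignment, for validating the seeded mapper.

This module deliberately skips everything heuristic: no seeds, no chains,
no band.  For each phase it fills the full affine-gap dynamic program of
the read against an entire reference sequence (global in the read, free
at both reference ends) and reports the best score over every position
and both phases.  It shares the scoring model with the mapper — match on
identity or an allowed bisulfite pairing (reference C/read T in the CT
phase, reference G/read A in the GA phase), mismatch otherwise, affine
gaps that never abut — but none of its code, so agreement between the
two is a meaningful check.  Quadratic time; intended for kilobase-scale
references only.
"""

from __future__ import annotations

import numpy as np

from .bsalign import MapperParams
from .refdata import ReferenceGenome

_NEG = -(10**9)


def _full_dp_best(read: str, ref: str, phase: str, params: MapperParams) -> int:
    """Best affine-gap score of the whole read anywhere in ``ref``."""
    L, W = len(read), len(ref)
    if L == 0 or W == 0:
        return _NEG
    refb = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    mt, mm = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend

    m_prev = np.zeros(W + 1, dtype=np.int64)  # row 0: free reference start
    x_prev = np.full(W + 1, _NEG, dtype=np.int64)
    y_prev = np.full(W + 1, _NEG, dtype=np.int64)
    jj = np.arange(W, dtype=np.int64)
    for i in range(1, L + 1):
        q = read[i - 1]
        ok = refb == ord(q)
        if phase == "CT" and q == "T":
            ok = ok | (refb == ord("C"))
        elif phase == "GA" and q == "A":
            ok = ok | (refb == ord("G"))
        if q == "N":
            ok = np.zeros(W, dtype=bool)
        else:
            ok = ok & (refb != ord("N"))
        s = np.where(ok, mt, mm)

        m_cur = np.full(W + 1, _NEG, dtype=np.int64)
        best_prev = np.maximum(np.maximum(m_prev, x_prev), y_prev)
        m_cur[1:] = s + best_prev[:-1]
        x_cur = np.maximum(m_prev + go, x_prev + ge)
        # gap in read (consumes reference), opened from m_cur in-row
        d = m_cur[:-1] + go - ge * (jj + 1)
        acc = np.maximum.accumulate(d)
        y_cur = np.full(W + 1, _NEG, dtype=np.int64)
        y_cur[1:] = acc + ge * (jj + 1)
        m_prev, x_prev, y_prev = m_cur, x_cur, y_cur
    return int(np.maximum(m_prev, x_prev).max())


def exhaustive_best_score(
    read: str,
    genome: ReferenceGenome,
    params: MapperParams | None = None,
) -> int:
    """Best two-phase score of the read over every genome position."""
    params = params if params is not None else MapperParams()
    best = _NEG
    for seq in genome.chromosomes.values():
        for phase in ("CT", "GA"):
            best = max(best, _full_dp_best(read, seq, phase, params))
    return best
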