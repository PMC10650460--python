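"""Anchored isomiR decomposition against a mature-within-hairpin annotation.

Each read is explained as the mature sequence with, possibly, a 5′ start
shift, a templated 3′ trim or extension, a non-templated 3′ tail and a small
number of internal substitutions. The decomposition is *normative* rather
than heuristic: candidate 5′ shifts are enumerated within a window, the 3′
overhang beyond the mature end is split by greedy maximal templated matching
against the hairpin's downstream context (matched prefix → templated
extension, remainder → non-templated tail), and the candidate minimizing the
total edit count

    |shift5| + trim3 + ext3 + |tail| + #substitutions

wins, with ties broken by smaller |shift5|, then smaller |tail|, then
lexicographic mature id. This makes isoform assignment deterministic and
reproducible, which a black-box aligner is not.

Labels follow the field's descriptive vocabulary: "canonical", "Plus A" for a
non-templated adenosine tail, "Trim A" / "Trim AG" / "Trim AGU" for 3′
deletions named by the removed bases from the terminus inward, "Ext+n" for
templated extensions, a "5p±n" prefix for 5′ variants and ";sub<pos><ref>><alt>"
suffixes for substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .qc import CollapsedRead
from .reference import HairpinRef, MatureAnnotation, ReferenceSet

READ_MIN_LEN = 15
READ_MAX_LEN = 30


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class CallerParams:
    """Decomposition limits.

    ``core_start``/``core_end`` bound the mismatch-free anchor region in
    0-based mature coordinates; it must contain the seed (mature positions
    1–7), which every 3′ isomiR shares with its canonical form. When a mature
    is shorter than ``core_end`` the core is clipped to the mature interval.
    """

    max_5p_shift: int = 2
    max_3p_trim: int = 5
    max_3p_ext: int = 5
    max_mismatch: int = 1
    core_start: int = 1
    core_end: int = 18
    allow_trim_tail: bool = False

    def __post_init__(self) -> None:
        for name in ("max_5p_shift", "max_3p_trim", "max_3p_ext", "max_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.core_start < self.core_end):
            raise ValueError("require 0 <= core_start < core_end")
        if self.core_start > 1 or self.core_end < 8:
            raise ValueError("core region must contain seed positions 1-7")


@dataclass(frozen=True)
class IsomiRCall:
    """A read's decomposition against one mature annotation.

    shift5: read 5′ start minus mature start (negative = 5′ extension,
    positive = 5′ trim). trim3/ext3: templated bases removed from / appended
    beyond the mature 3′ end (at most one nonzero). tail: non-templated 3′
    addition. substitutions: (position within read, ref base, read base).
    """

    sequence: str
    mature_id: str
    shift5: int
    trim3: int
    ext3: int
    tail: str
    substitutions: tuple[tuple[int, str, str], ...]
    label: str

    @property
    def edits(self) -> int:
        return (
            abs(self.shift5)
            + self.trim3
            + self.ext3
            + len(self.tail)
            + len(self.substitutions)
        )

    @property
    def is_canonical(self) -> bool:
        return self.label == "canonical"


def _label(
    mature_seq: str,
    shift5: int,
    trim3: int,
    ext3: int,
    tail: str,
    substitutions: Sequence[tuple[int, str, str]],
) -> str:
    parts: list[str] = []
    if shift5 != 0:
        parts.append(f"5p{shift5:+d}")
    if trim3 > 0:
        removed = mature_seq[len(mature_seq) - trim3 :][::-1]
        parts.append(f"Trim {removed}")
    if ext3 > 0:
        parts.append(f"Ext+{ext3}")
    if tail:
        parts.append(f"Plus {tail}")
    base = " ".join(parts) if parts else "canonical"
    for pos, ref, alt in substitutions:
        base += f";sub{pos}{ref}>{alt}"
    return base


def structural_class(label: str) -> str:
    """The 5′/3′ structural class of a label, substitution suffixes stripped.

    Substitutions are typically sequencing noise on top of a structural
    isoform, so proportion-recovery comparisons aggregate over them:
    "canonical;sub21A>G" → "canonical", "Trim A;sub3C>U" → "Trim A".
    """
    return label.split(";sub", 1)[0]


def label_call(call: IsomiRCall, ref: ReferenceSet) -> str:
    """Recompute the descriptive label from a call's fields."""
    return _label(
        ref.mature_sequence(call.mature_id),
        call.shift5,
        call.trim3,
        call.ext3,
        call.tail,
        call.substitutions,
    )


def _decompose_at(
    seq: str,
    hairpin: HairpinRef,
    annot: MatureAnnotation,
    shift5: int,
    params: CallerParams,
) -> Optional[IsomiRCall]:
    """Deterministic decomposition at a fixed 5′ shift, or None if outside limits."""
    hp = hairpin.sequence
    s = annot.start + shift5
    if s < 0:
        return None
    mat_len = annot.end - annot.start
    core_lo = params.core_start
    core_hi = min(params.core_end, mat_len)

    if s + len(seq) <= annot.end:
        trim3 = annot.end - (s + len(seq))
        if trim3 > params.max_3p_trim:
            return None
        ext3, tail = 0, ""
        body_len = len(seq)
    else:
        trim3 = 0
        body_len = annot.end - s
        if body_len < 0:
            return None
        overhang = seq[body_len:]
        ctx = hp[annot.end :]
        ext3 = 0
        while (
            ext3 < len(overhang)
            and ext3 < len(ctx)
            and ext3 < params.max_3p_ext
            and overhang[ext3] == ctx[ext3]
        ):
            ext3 += 1
        tail = overhang[ext3:]
        if len(tail) > params.max_3p_ext:
            return None

    if s + body_len > len(hp):
        return None

    subs: list[tuple[int, str, str]] = []
    for i in range(body_len):
        ref_base = hp[s + i]
        if seq[i] != ref_base:
            mat_pos = s + i - annot.start
            if core_lo <= mat_pos < core_hi:
                return None
            subs.append((i, ref_base, seq[i]))
    if len(subs) > params.max_mismatch:
        return None

    mature_seq = hp[annot.start : annot.end]
    return IsomiRCall(
        sequence=seq,
        mature_id=annot.mature_id,
        shift5=shift5,
        trim3=trim3,
        ext3=ext3,
        tail=tail,
        substitutions=tuple(subs),
        label=_label(mature_seq, shift5, trim3, ext3, tail, subs),
    )


def _decompose_trim_tail_at(
    seq: str,
    hairpin: HairpinRef,
    annot: MatureAnnotation,
    shift5: int,
    tail_len: int,
    params: CallerParams,
) -> Optional[IsomiRCall]:
    """Trim-then-tail variant (non-templated tail after a 3′ trim).

    Only enumerated when ``allow_trim_tail`` is set; the four isoform classes
    observed in heart small-RNA data never combine them, so this is off by
    default.
    """
    hp = hairpin.sequence
    s = annot.start + shift5
    if s < 0 or tail_len <= 0 or tail_len > params.max_3p_ext:
        return None
    body_len = len(seq) - tail_len
    trim3 = annot.end - (s + body_len)
    if trim3 <= 0 or trim3 > params.max_3p_trim:
        return None
    if s + body_len > len(hp):
        return None
    tail = seq[body_len:]
    mat_len = annot.end - annot.start
    core_lo, core_hi = params.core_start, min(params.core_end, mat_len)
    subs: list[tuple[int, str, str]] = []
    for i in range(body_len):
        ref_base = hp[s + i]
        if seq[i] != ref_base:
            mat_pos = s + i - annot.start
            if core_lo <= mat_pos < core_hi:
                return None
            subs.append((i, ref_base, seq[i]))
    if len(subs) > params.max_mismatch:
        return None
    mature_seq = hp[annot.start : annot.end]
    return IsomiRCall(
        sequence=seq,
        mature_id=annot.mature_id,
        shift5=shift5,
        trim3=trim3,
        ext3=0,
        tail=tail,
        substitutions=tuple(subs),
        label=_label(mature_seq, shift5, trim3, 0, tail, subs),
    )


def _call_key(call: IsomiRCall) -> tuple:
    return (call.edits, abs(call.shift5), len(call.tail), call.mature_id)


def decompose(
    seq: str,
    hairpin: HairpinRef,
    annot: MatureAnnotation,
    params: CallerParams = CallerParams(),
) -> Optional[IsomiRCall]:
    """Best decomposition of ``seq`` against one mature annotation, or None.

    Enumerates 5′ shifts in [-max_5p_shift, +max_5p_shift]; at each shift the
    decomposition is unique (greedy maximal templated 3′ matching); the
    minimum-edit candidate wins with ties to smaller |shift5| then smaller
    |tail|.
    """
    if not (READ_MIN_LEN <= len(seq) <= READ_MAX_LEN):
        raise CallerError(
            f"read length {len(seq)} outside [{READ_MIN_LEN}, {READ_MAX_LEN}]"
        )
    best: Optional[IsomiRCall] = None
    for shift5 in range(-params.max_5p_shift, params.max_5p_shift + 1):
        candidates = [_decompose_at(seq, hairpin, annot, shift5, params)]
        if params.allow_trim_tail:
            candidates.extend(
                _decompose_trim_tail_at(seq, hairpin, annot, shift5, L, params)
                for L in range(1, params.max_3p_ext + 1)
            )
        for cand in candidates:
            if cand is not None and (
                best is None or _call_key(cand) < _call_key(best)
            ):
                best = cand
    return best


def reconstruct(call: IsomiRCall, ref: ReferenceSet) -> str:
    """Rebuild the read from the reference; round-trip oracle for decompose."""
    annot = ref.matures.get(call.mature_id)
    if annot is None:
        raise CallerError(f"unknown mature id {call.mature_id!r}")
    hp = ref.hairpins[annot.hairpin_id].sequence
    if call.trim3 and call.ext3:
        raise CallerError("at most one of trim3/ext3 may be nonzero")
    start = annot.start + call.shift5
    end = annot.end - call.trim3 + call.ext3
    if start < 0 or end > len(hp) or start >= end:
        raise CallerError("call interval outside hairpin")
    templated = list(hp[start:end])
    for pos, ref_base, alt in call.substitutions:
        if pos < 0 or pos >= len(templated):
            raise CallerError(f"substitution position {pos} outside templated span")
        if templated[pos] != ref_base:
            raise CallerError(
                f"substitution ref base mismatch at {pos}: "
                f"expected {templated[pos]}, call says {ref_base}"
            )
        templated[pos] = alt
    return "".join(templated) + call.tail


@dataclass
class IsomiRProfile:
    """Per-sample isoform abundance: (mature_id, label) → read count, plus RPM
    over assigned reads."""

    sample_id: str
    entries: dict[tuple[str, str], int] = field(default_factory=dict)
    calls: dict[tuple[str, str], IsomiRCall] = field(default_factory=dict)
    total_assigned: int = 0
    total_unassigned: int = 0

    @property
    def rpm(self) -> dict[tuple[str, str], float]:
        if self.total_assigned == 0:
            return {}
        return {
            key: 1e6 * n / self.total_assigned for key, n in self.entries.items()
        }

    def labels(self, mature_id: str) -> list[str]:
        return [lab for (mid, lab) in self.entries if mid == mature_id]

    def add(self, call: IsomiRCall, count: int) -> None:
        key = (call.mature_id, call.label)
        self.entries[key] = self.entries.get(key, 0) + count
        self.calls.setdefault(key, call)
        self.total_assigned += count

    def to_frame(self) -> pd.DataFrame:
        rpm = self.rpm
        rows = []
        for (mid, label), n in sorted(
            self.entries.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            call = self.calls[(mid, label)]
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "mature_id": mid,
                    "label": label,
                    "shift5": call.shift5,
                    "trim3": call.trim3,
                    "ext3": call.ext3,
                    "tail": call.tail,
                    "n_sub": len(call.substitutions),
                    "count": n,
                    "rpm": rpm[(mid, label)],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "mature_id",
                "label",
                "shift5",
                "trim3",
                "ext3",
                "tail",
                "n_sub",
                "count",
                "rpm",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "IsomiRProfile":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"tail": str})
        sample_id = str(df["sample_id"].iloc[0]) if len(df) else ""
        prof = cls(sample_id=sample_id)
        for _, row in df.iterrows():
            key = (str(row["mature_id"]), str(row["label"]))
            prof.entries[key] = int(row["count"])
            prof.total_assigned += int(row["count"])
        return prof


def call_sample(
    collapsed: Iterable[CollapsedRead],
    ref: ReferenceSet,
    params: CallerParams = CallerParams(),
    sample_id: str = "sample",
) -> IsomiRProfile:
    """Decompose each unique sequence against every mature; count whole reads.

    Across matures the usual tie-break applies with lexicographic mature id
    last. No-calls accumulate in total_unassigned.
    """
    if not ref.matures:
        raise CallerError("empty reference set")
    profile = IsomiRProfile(sample_id=sample_id)
    for cr in collapsed:
        best: Optional[IsomiRCall] = None
        for mature_id in sorted(ref.matures):
            annot = ref.matures[mature_id]
            hairpin = ref.hairpins[annot.hairpin_id]
            try:
                cand = decompose(cr.sequence, hairpin, annot, params)
            except CallerError:
                cand = None
            if cand is not None and (
                best is None or _call_key(cand) < _call_key(best)
            ):
                best = cand
        if best is None:
            profile.total_unassigned += cr.count
        else:
            profile.add(best, cr.count)
    return profile


def rank_isoforms(
    profile: IsomiRProfile, mature_id: str, n: int
) -> list[tuple[str, int]]:
    """Top-n isoforms of one mature by count; ties broken lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mature_id not in {mid for (mid, _) in profile.entries}:
        raise CallerError(f"mature id {mature_id!r} not present in profile")
    items = [
        (label, count)
        for (mid, label), count in profile.entries.items()
        if mid == mature_id
    ]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return items[:n]


def write_mirgff3(profile: IsomiRProfile, ref: ReferenceSet, path: str | Path) -> None:
    """Write one mirGFF3-flavored line per isoform with a Variant= attribute."""
    with open(path, "w") as fh:
        fh.write("## mirGFF3-flavored isomiR output\n")
        for (mid, label), count in sorted(profile.entries.items()):
            call = profile.calls.get((mid, label))
            if call is None:
                continue
            annot = ref.matures[mid]
            variants = []
            if call.shift5 != 0:
                variants.append(f"iso_5p:{-call.shift5:+d}")
            if call.trim3:
                variants.append(f"iso_3p:-{call.trim3}")
            if call.ext3:
                variants.append(f"iso_3p:+{call.ext3}")
            if call.tail:
                variants.append(f"iso_add3p:{len(call.tail)}")
            if call.substitutions:
                variants.append("iso_snv")
            variant = ",".join(variants) if variants else "NA"
            start = annot.start + call.shift5 + 1
            end = annot.end - call.trim3 + call.ext3 + len(call.tail)
            fh.write(
                f"{annot.hairpin_id}\tisomirkit\tisomiR\t{start}\t{end}\t.\t+\t.\t"
                f"ID={mid}.{label.replace(' ', '_')};Parent={mid};"
                f"Variant={variant};Expression={count}\n"
            )
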