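"""miRBase-dialect reference model: hairpins and mature-within-hairpin coordinates.

The hairpin (pre-miRNA) sequence is the templated universe for every
downstream 3′ classification: an extension beyond the mature 3′ end that
matches the hairpin is *templated* (imprecise Drosha/Dicer cleavage), while
bases absent from the hairpin at that position are a *non-templated tail*
(nucleotidyl-transferase addition). Coordinates are 0-based half-open on the
hairpin's 5′→3′ strand; genomic flank beyond the hairpin is not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

MATURE_MIN_LEN = 15
MATURE_MAX_LEN = 30


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and convert T→U; reject characters outside {A,C,G,U}."""
    s = str(seq).upper().replace("T", "U")
    for i, base in enumerate(s):
        if base not in RNA_ALPHABET:
            raise ReferenceError(
                f"{context}: invalid character {base!r} at position {i}"
            )
    return s


@dataclass(frozen=True)
class HairpinRef:
    """A pre-miRNA hairpin sequence in RNA alphabet."""

    hairpin_id: str
    sequence: str
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"hairpin {self.hairpin_id!r}: empty sequence")
        object.__setattr__(
            self, "sequence", normalize_rna(self.sequence, context=self.hairpin_id)
        )
        if not self.species_tag and "-" in self.hairpin_id:
            object.__setattr__(
                self, "species_tag", self.hairpin_id.split("-", 1)[0]
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """Interval of a mature miRNA inside its parental hairpin.

    ``arm`` records which hairpin arm the mature is excised from: 5p when the
    interval midpoint falls in the first half of the hairpin, 3p otherwise.
    """

    mature_id: str
    hairpin_id: str
    start: int
    end: int
    arm: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ReferenceError(
                f"mature {self.mature_id!r}: invalid interval [{self.start}, {self.end})"
            )
        length = self.end - self.start
        if not (MATURE_MIN_LEN <= length <= MATURE_MAX_LEN):
            raise ReferenceError(
                f"mature {self.mature_id!r}: length {length} outside "
                f"[{MATURE_MIN_LEN}, {MATURE_MAX_LEN}]"
            )
        if self.arm not in ("5p", "3p", "unknown"):
            raise ReferenceError(f"mature {self.mature_id!r}: bad arm {self.arm!r}")

    def __len__(self) -> int:
        return self.end - self.start


def load_hairpin_fasta(path: str | Path) -> list[HairpinRef]:
    """Load hairpins from a miRBase-style FASTA (id = first header token).

    Sequences are uppercased and T→U normalized; duplicate ids are rejected.
    """
    path = Path(path)
    hairpins: list[HairpinRef] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, AssertionError) as exc:  # biopython parse failure
        raise ReferenceError(f"{path}: malformed FASTA ({exc})") from exc
    if not records:
        raise ReferenceError(f"{path}: no FASTA records")
    for rec in records:
        if rec.id in seen:
            raise ReferenceError(f"{path}: duplicate hairpin id {rec.id!r}")
        seen.add(rec.id)
        hairpins.append(HairpinRef(rec.id, str(rec.seq)))
    return hairpins


def locate_mature(mature_seq: str, hairpin: HairpinRef, mature_id: str = "") -> MatureAnnotation:
    """Recover mature coordinates by exact substring search within the hairpin.

    miRBase mature FASTA carries no coordinates; the leftmost exact occurrence
    is used. Multiple occurrences log a warning; absence raises.
    """
    mature_seq = normalize_rna(mature_seq, context=mature_id or "mature")
    if not (MATURE_MIN_LEN <= len(mature_seq) <= MATURE_MAX_LEN):
        raise ReferenceError(
            f"mature sequence length {len(mature_seq)} outside "
            f"[{MATURE_MIN_LEN}, {MATURE_MAX_LEN}]"
        )
    occurrences = []
    pos = hairpin.sequence.find(mature_seq)
    while pos != -1:
        occurrences.append(pos)
        pos = hairpin.sequence.find(mature_seq, pos + 1)
    if not occurrences:
        raise ReferenceError(
            f"mature {mature_id or mature_seq!r} not found in hairpin "
            f"{hairpin.hairpin_id!r}"
        )
    if len(occurrences) > 1:
        logger.warning(
            "mature %s occurs %d times in hairpin %s; using leftmost at %d",
            mature_id or mature_seq,
            len(occurrences),
            hairpin.hairpin_id,
            occurrences[0],
        )
    start = occurrences[0]
    end = start + len(mature_seq)
    midpoint = (start + end) / 2
    arm = "5p" if midpoint < len(hairpin) / 2 else "3p"
    return MatureAnnotation(
        mature_id=mature_id or f"{hairpin.hairpin_id}-mature",
        hairpin_id=hairpin.hairpin_id,
        start=start,
        end=end,
        arm=arm,
    )


@dataclass
class ReferenceSet:
    """Hairpins plus mature annotations; every annotation resolves to a hairpin."""

    hairpins: dict[str, HairpinRef] = field(default_factory=dict)
    matures: dict[str, MatureAnnotation] = field(default_factory=dict)

    def add_hairpin(self, hairpin: HairpinRef) -> None:
        if hairpin.hairpin_id in self.hairpins:
            raise ReferenceError(f"duplicate hairpin id {hairpin.hairpin_id!r}")
        self.hairpins[hairpin.hairpin_id] = hairpin

    def add_mature(self, annot: MatureAnnotation) -> None:
        if annot.mature_id in self.matures:
            raise ReferenceError(f"duplicate mature id {annot.mature_id!r}")
        hairpin = self.hairpins.get(annot.hairpin_id)
        if hairpin is None:
            raise ReferenceError(
                f"mature {annot.mature_id!r} refers to unknown hairpin "
                f"{annot.hairpin_id!r}"
            )
        if annot.end > len(hairpin):
            raise ReferenceError(
                f"mature {annot.mature_id!r} interval exceeds hairpin length"
            )
        self.matures[annot.mature_id] = annot

    def _annotation(self, mature_id: str) -> MatureAnnotation:
        try:
            return self.matures[mature_id]
        except KeyError:
            raise ReferenceError(f"unknown mature id {mature_id!r}") from None

    def hairpin_of(self, mature_id: str) -> HairpinRef:
        return self.hairpins[self._annotation(mature_id).hairpin_id]

    def mature_sequence(self, mature_id: str) -> str:
        """The canonical mature sequence: hairpin[start:end]."""
        annot = self._annotation(mature_id)
        return self.hairpins[annot.hairpin_id].sequence[annot.start : annot.end]

    def downstream_context(self, mature_id: str, k: int) -> str:
        """Up to ``k`` hairpin bases immediately 3′ of the mature end.

        Shorter than ``k`` (possibly empty) when the mature abuts the
        hairpin's 3′ terminus; this is the templated universe for extensions.
        """
        if k < 0:
            raise ValueError("k must be >= 0")
        annot = self._annotation(mature_id)
        hp = self.hairpins[annot.hairpin_id]
        return hp.sequence[annot.end : annot.end + k]

    @classmethod
    def from_fasta(
        cls, hairpin_path: str | Path, mature_path: str | Path
    ) -> "ReferenceSet":
        """Build from a miRBase-style hairpin FASTA plus mature FASTA.

        Each mature is located by exact search; when it occurs in several
        hairpins the lexicographically first hairpin id wins (warning logged).
        """
        ref = cls()
        for hp in load_hairpin_fasta(hairpin_path):
            ref.add_hairpin(hp)
        mature_records = list(SeqIO.parse(str(mature_path), "fasta"))
        if not mature_records:
            raise ReferenceError(f"{mature_path}: no FASTA records")
        for rec in mature_records:
            hits = []
            for hp_id in sorted(ref.hairpins):
                hp = ref.hairpins[hp_id]
                if normalize_rna(str(rec.seq), context=rec.id) in hp.sequence:
                    hits.append(hp)
            if not hits:
                raise ReferenceError(
                    f"mature {rec.id!r} not found in any hairpin"
                )
            if len(hits) > 1:
                logger.warning(
                    "mature %s found in %d hairpins; using %s",
                    rec.id,
                    len(hits),
                    hits[0].hairpin_id,
                )
            ref.add_mature(locate_mature(str(rec.seq), hits[0], rec.id))
        return ref

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "hairpin_id": a.hairpin_id,
                "mature_id": a.mature_id,
                "start": a.start,
                "end": a.end,
                "arm": a.arm,
                "mature_seq": self.mature_sequence(a.mature_id),
            }
            for a in self.matures.values()
        ]
        return pd.DataFrame(
            rows, columns=["hairpin_id", "mature_id", "start", "end", "arm", "mature_seq"]
        )

    def write_summary(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_fasta(self, hairpin_path: str | Path, mature_path: str | Path) -> None:
        """Write hairpins and mature sequences back out; round-trips exactly."""
        with open(hairpin_path, "w") as fh:
            for hp in self.hairpins.values():
                fh.write(f">{hp.hairpin_id}\n{hp.sequence}\n")
        with open(mature_path, "w") as fh:
            for mid in self.matures:
                fh.write(f">{mid}\n{self.mature_sequence(mid)}\n")


def load_mature_gff3(path: str | Path, ref: ReferenceSet) -> None:
    """Optional GFF3 override for mature coordinates.

    Expects miRBase-style rows whose seqid is a loaded hairpin id, with ``ID``
    (mature id) and optionally ``Derives_from`` attributes; coordinates are
    1-based inclusive in GFF3 and converted to the 0-based half-open frame.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ReferenceError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("miRNA", "mature_miRNA"):
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            mature_id = attr_map.get("ID")
            if mature_id is None:
                raise ReferenceError(f"{path}:{lineno}: missing ID attribute")
            hairpin_id = attr_map.get("Derives_from", seqid)
            annot = MatureAnnotation(
                mature_id=mature_id,
                hairpin_id=hairpin_id,
                start=int(start) - 1,
                end=int(end),
                arm=attr_map.get("arm", "unknown"),
            )
            if mature_id in ref.matures:
                del ref.matures[mature_id]
            ref.add_mature(annot)
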