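"""Synthetic small-RNA reads and count matrices with planted ground truth.

Every pipeline stage is testable without downloads: a random hairpin with an
annotated mature interval, reads drawn from a planted isoform-class
distribution with substitution-type sequencing error and Phred qualities,
and negative-binomial count matrices with planted up/down gene sets whose
overlap structure across treatments is known exactly.

The read generator plants the isoform classes observed for cardiac
miR-125b: canonical, a non-templated 3′ adenosine (Plus A), 3′ trims of one
to three bases (Trim A / Trim AG / Trim AGU — the synthetic mature is forced
to end ...UGA so the trim labels match), and a one-base templated extension
(Ext+1). The hairpin base immediately 3′ of the mature is forced to differ
from the tail nucleotide, so the planted tail is non-templated by
construction. The error model is substitution-only: indel errors would be
confounded with trim/extension classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .qc import ReadRecord
from .reference import HairpinRef, MatureAnnotation, ReferenceSet

RNA_BASES = ("A", "C", "G", "U")


class SimConfigError(ValueError):
    pass


def _default_proportions() -> dict[str, float]:
    # Canonical plus the five next most abundant planted isoform classes;
    # trims dominate additions, mirroring heart small-RNA profiles where
    # 3′-trimmed isoforms can out-rank the canonical read.
    return {
        "canonical": 0.30,
        "Trim A": 0.25,
        "Plus A": 0.20,
        "Trim AG": 0.10,
        "Trim AGU": 0.10,
        "Ext+1": 0.05,
    }


@dataclass
class SimConfig:
    """Generative specification for synthetic isomiR-bearing reads."""

    seed: int = 0
    n_reads: int = 10_000
    isomir_proportions: dict[str, float] = field(default_factory=_default_proportions)
    seq_error_rate: float = 0.005
    phred_mean: float = 35.0
    phred_sd: float = 3.0
    mature_len: int = 22
    flank5: int = 8
    flank3: int = 8
    tail_nt: str = "A"

    def __post_init__(self) -> None:
        total = sum(self.isomir_proportions.values())
        if any(p < 0 for p in self.isomir_proportions.values()):
            raise SimConfigError("proportions must be >= 0")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SimConfigError(f"proportions must sum to 1 (got {total})")
        if not (20 <= self.mature_len <= 24):
            raise SimConfigError("mature_len must lie in [20, 24]")
        if self.flank5 < 3 or self.flank3 < 3:
            raise SimConfigError("flank5 and flank3 must be >= 3 (templated context)")
        if not (0.0 <= self.seq_error_rate < 1.0):
            raise SimConfigError("seq_error_rate must lie in [0, 1)")
        if self.tail_nt not in RNA_BASES:
            raise SimConfigError("tail_nt must be one of A/C/G/U")


def make_reference(config: SimConfig) -> tuple[HairpinRef, MatureAnnotation]:
    """Random hairpin = flank5 + mature + flank3 with a planted mature interval.

    The mature ends ...UGA (so one/two/three-base trims are named Trim A /
    Trim AG / Trim AGU) and the first 3′-flank base differs from
    ``tail_nt``, making a planted "Plus <tail_nt>" read non-templated. The
    mature is guaranteed to occur exactly once in the hairpin.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(100):
        mature = "".join(rng.choice(RNA_BASES, size=config.mature_len - 3)) + "UGA"
        flank5 = "".join(rng.choice(RNA_BASES, size=config.flank5))
        non_tail = [b for b in RNA_BASES if b != config.tail_nt]
        flank3 = str(rng.choice(non_tail)) + "".join(
            rng.choice(RNA_BASES, size=config.flank3 - 1)
        )
        hairpin_seq = flank5 + mature + flank3
        if hairpin_seq.count(mature) == 1:
            hairpin = HairpinRef(f"sim-mir-s{config.seed}", hairpin_seq, "sim")
            annot = MatureAnnotation(
                mature_id=f"sim-miR-s{config.seed}-5p",
                hairpin_id=hairpin.hairpin_id,
                start=config.flank5,
                end=config.flank5 + config.mature_len,
                arm="5p",
            )
            return hairpin, annot
    raise SimConfigError("could not generate a hairpin with a unique mature")


def reference_set(hairpin: HairpinRef, annot: MatureAnnotation) -> ReferenceSet:
    ref = ReferenceSet()
    ref.add_hairpin(hairpin)
    ref.add_mature(annot)
    return ref


def _class_sequence(
    cls_name: str, hairpin: HairpinRef, annot: MatureAnnotation, config: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Exact (error-free) sequence for a planted class and its expected label."""
    hp = hairpin.sequence
    mature = hp[annot.start : annot.end]
    if cls_name == "canonical":
        return mature, "canonical"
    if cls_name.startswith("Plus "):
        tail = cls_name.split(" ", 1)[1]
        if tail[0] == hp[annot.end]:
            raise SimConfigError(
                f"planted tail {tail!r} would be templated at this hairpin"
            )
        return mature + tail, cls_name
    if cls_name.startswith("Trim "):
        removed = cls_name.split(" ", 1)[1]
        k = len(removed)
        if mature[-k:][::-1] != removed:
            raise SimConfigError(
                f"class {cls_name!r} inconsistent with mature ending {mature[-3:]!r}"
            )
        return mature[:-k], cls_name
    if cls_name.startswith("Ext+"):
        k = int(cls_name[4:])
        ext = hp[annot.end : annot.end + k]
        if len(ext) < k:
            raise SimConfigError(f"not enough 3′ flank for {cls_name}")
        return mature + ext, cls_name
    if cls_name == "5p+1":
        return mature[1:], "5p+1"
    if cls_name == "5p-1":
        if annot.start < 1:
            raise SimConfigError("no 5′ flank for 5p-1 class")
        return hp[annot.start - 1 : annot.end], "5p-1"
    if cls_name == "sub":
        pos = len(mature) - 2  # outside the default mismatch-free core
        ref_base = mature[pos]
        alt = str(rng.choice([b for b in RNA_BASES if b != ref_base]))
        seq = mature[:pos] + alt + mature[pos + 1 :]
        return seq, f"canonical;sub{pos}{ref_base}>{alt}"
    raise SimConfigError(f"unknown planted class {cls_name!r}")


def sample_reads(
    config: SimConfig, hairpin: HairpinRef, annot: MatureAnnotation
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw reads from the planted class distribution with per-base errors.

    Returns the reads plus a truth table with one row per read: planted
    class, the label an error-free copy would receive, and whether any
    sequencing error was applied. Fully deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    classes = list(config.isomir_proportions)
    probs = np.array([config.isomir_proportions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(classes), size=config.n_reads, p=probs)

    reads: list[ReadRecord] = []
    truth_rows = []
    for i, ci in enumerate(draws):
        cls_name = classes[int(ci)]
        seq, expected_label = _class_sequence(cls_name, hairpin, annot, config, rng)
        errored = False
        if config.seq_error_rate > 0:
            bases = list(seq)
            hits = rng.random(len(bases)) < config.seq_error_rate
            for j in np.nonzero(hits)[0]:
                bases[j] = str(
                    rng.choice([b for b in RNA_BASES if b != bases[j]])
                )
                errored = True
            seq = "".join(bases)
        quals = np.clip(
            np.rint(rng.normal(config.phred_mean, config.phred_sd, size=len(seq))),
            2,
            41,
        ).astype(int)
        read_id = f"r{i:06d}"
        reads.append(ReadRecord(read_id, seq, tuple(int(q) for q in quals)))
        truth_rows.append(
            {
                "read_id": read_id,
                "class": cls_name,
                "expected_label": expected_label,
                "errored": errored,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "class", "expected_label", "errored"]
    )
    return reads, truth


DEFAULT_GROUPS = ("MC", "miR", "PlusA", "TrimA", "TrimAG", "TrimAGU")


def default_planted_sets(n_genes: int) -> dict[str, tuple[set[str], set[str]]]:
    """Planted (up, down) gene sets with a concordant/divergent overlap design.

    miR, PlusA and TrimA share a large common core of regulated genes with
    small private sets; TrimAG and TrimAGU share a separate, larger core that
    is disjoint from the first — the qualitative structure in which
    one-base 3′ variants act concordantly with the canonical miRNA while
    deeper trims diverge.
    """
    if n_genes < 900:
        raise SimConfigError("default design needs at least 900 genes")
    ids = [f"g{i:05d}" for i in range(n_genes)]

    def block(a: int, b: int) -> set[str]:
        return set(ids[a:b])

    down_core_abc = block(0, 120)
    down_priv = {"miR": block(120, 140), "PlusA": block(140, 160), "TrimA": block(160, 180)}
    down_core_de = block(180, 380)
    down_priv["TrimAG"] = block(380, 430)
    down_priv["TrimAGU"] = block(430, 480)

    up_core_abc = block(480, 580)
    up_priv = {"miR": block(580, 595), "PlusA": block(595, 610), "TrimA": block(610, 625)}
    up_core_de = block(625, 775)
    up_priv["TrimAG"] = block(775, 805)
    up_priv["TrimAGU"] = block(805, 835)

    planted: dict[str, tuple[set[str], set[str]]] = {"MC": (set(), set())}
    for t in ("miR", "PlusA", "TrimA"):
        planted[t] = (up_core_abc | up_priv[t], down_core_abc | down_priv[t])
    for t in ("TrimAG", "TrimAGU"):
        planted[t] = (up_core_de | up_priv[t], down_core_de | down_priv[t])
    return planted


def planted_overlap_design(
    planted_sets: dict[str, tuple[set[str], set[str]]], direction: str = "down"
) -> dict[tuple[str, str], int]:
    """Pairwise planted intersection sizes (truth for overlap-recovery tests)."""
    idx = 1 if direction == "down" else 0
    names = [t for t in planted_sets if planted_sets[t][idx]]
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = len(planted_sets[a][idx] & planted_sets[b][idx])
    return out


@dataclass
class CountSimConfig:
    """Generative specification for planted-DE count matrices."""

    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    groups: tuple[str, ...] = DEFAULT_GROUPS
    planted_sets: Optional[dict[str, tuple[set[str], set[str]]]] = None
    overlap_design: Optional[dict[tuple[str, str], int]] = None
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    lfc_magnitude: float = 1.5

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise SimConfigError("need >= 2 replicates per group")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if self.planted_sets is None:
            self.planted_sets = default_planted_sets(self.n_genes)
        universe = {f"g{i:05d}" for i in range(self.n_genes)}
        for t, (up, down) in self.planted_sets.items():
            if t not in self.groups:
                raise SimConfigError(f"planted treatment {t!r} not in groups")
            if not (up <= universe and down <= universe):
                raise SimConfigError(f"planted genes for {t!r} outside universe")
            if up & down:
                raise SimConfigError(f"up/down overlap for treatment {t!r}")
        if self.overlap_design is not None:
            actual = planted_overlap_design(self.planted_sets)
            for pair, size in self.overlap_design.items():
                if actual.get(pair, actual.get(pair[::-1], 0)) != size:
                    raise SimConfigError(
                        f"overlap_design infeasible for pair {pair}: "
                        f"planted sets give {actual.get(pair)}"
                    )


@dataclass
class CountSimResult:
    matrices: dict[str, pd.DataFrame]  # group → genes × replicates
    planted_sets: dict[str, tuple[set[str], set[str]]]
    gene_means: pd.Series


def simulate_counts(config: CountSimConfig) -> CountSimResult:
    """Negative-binomial count matrices with planted fold changes.

    Per-gene baseline means are lognormal around ``baseline_mean`` (clamped
    to >= 1); planted genes' means are scaled by 2^±lfc_magnitude in their
    treatment group. ``dispersion`` is the NB dispersion (variance
    μ + dispersion·μ²); dispersion == 0 is the exact zero-noise limit where
    counts are the floored means, so planted structure is recoverable exactly.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    base_means = np.maximum(
        rng.lognormal(mean=math.log(config.baseline_mean), sigma=1.0, size=config.n_genes),
        1.0,
    )
    gene_means = pd.Series(base_means, index=genes)

    matrices: dict[str, pd.DataFrame] = {}
    for group in config.groups:
        up, down = config.planted_sets.get(group, (set(), set()))
        mu = gene_means.copy()
        if up:
            mu.loc[sorted(up)] *= 2.0**config.lfc_magnitude
        if down:
            mu.loc[sorted(down)] *= 2.0**-config.lfc_magnitude
        cols = {}
        for r in range(config.n_replicates):
            col = f"{group}_r{r + 1}"
            if config.dispersion == 0:
                cols[col] = np.floor(mu.to_numpy()).astype(int)
            else:
                size = 1.0 / config.dispersion
                p = size / (size + mu.to_numpy())
                cols[col] = rng.negative_binomial(size, p)
        matrices[group] = pd.DataFrame(cols, index=genes)
    return CountSimResult(
        matrices=matrices, planted_sets=config.planted_sets, gene_means=gene_means
    )


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_count_matrices(result: CountSimResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for group, df in result.matrices.items():
        df.to_csv(out / f"counts_{group}.tsv", sep="\t")
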