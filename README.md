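# isomirkit

Detection, classification and cross-sample comparison of **isomiRs** — the
5′/3′ sequence variants of mature miRNAs seen in small RNA-seq — plus the
downstream gene-set machinery used to compare a canonical miRNA's
transcriptomic footprint with its isoforms'.

Small-RNA reads rarely match the deposited mature sequence exactly: 3′
trimming, templated 3′ extension (imprecise Drosha/Dicer cleavage),
non-templated 3′ tailing (e.g. a post-transcriptionally added adenosine)
and occasional 5′ shifts produce a family of isoforms that share the seed
region but can differ in stability and potency. `isomirkit` is for
researchers who need to (1) call and name these isoforms reproducibly from
FASTQ against a miRBase-style hairpin+mature reference, (2) compare isoform
profiles across samples or species, and (3) quantify how a miRNA's and its
isoforms' regulated gene sets overlap.

## The model in brief

A read `r` is explained against a mature interval `[s, e)` in hairpin `H` as

```
r = H[s + shift5 : e − trim3 + ext3]  (+ substitutions)  + tail
```

choosing the candidate that minimizes the edit count
`|shift5| + trim3 + ext3 + |tail| + #subs` (ties → smaller `|shift5|`, then
smaller `|tail|`). The 3′ overhang is split by greedy maximal matching
against the hairpin: hairpin-matching bases are a **templated** extension
(`Ext+n`), the remainder a **non-templated** tail (`Plus A`). Trims are
named by the removed bases from the terminus inward (`Trim A`, `Trim AG`,
`Trim AGU` for a mature ending `…UGA`). Downstream, gene sets are built
from DE tables at **fold change ≥ 1.5** (inclusive) with **BH-adjusted
p < 0.05** (strict), compared via exact 2–3-way Venn partitions, and qPCR
is quantified by **2^−ΔΔCt**. Everything is exercisable on synthetic data
with planted ground truth (`isomirkit.simulate`).

## Worked example

```python
import isomirkit as ik

cfg = ik.SimConfig(seed=42, n_reads=10_000, seq_error_rate=0.005)
hairpin, annot = ik.make_reference(cfg)
ref = ik.reference_set(hairpin, annot)

reads, truth = ik.sample_reads(cfg, hairpin, annot)
kept, stats = ik.filter_reads(reads, ik.QCParams())          # 15–30 nt, mean Q >= 20
profile = ik.call_sample(ik.collapse(kept), ref, sample_id="sim42")

for label, count in ik.rank_isoforms(profile, annot.mature_id, 6):
    print(label, count)
```

prints (planted truth in `truth["class"].value_counts()` for comparison):

```
canonical 2686      # planted 3001
Trim A 2220         # planted 2455
Plus A 1812         # planted 2030
Trim AG 930         # planted 1017
Trim AGU 895        # planted 992
Ext+1 475           # planted 505
```

The ranking reproduces the planted isoform distribution; the uniform
deficit is reads whose simulated sequencing error hit the seed-containing
anchor region (no-calls: 791 of 10,000 here), and error-free recovery is
exact. The same decomposition applied to another species' canonical mature
expresses cross-species relations — a one-base-shorter canonical comes back
`Trim A`, a non-templated one-base addition `Plus A`
(`examples/02_cross_species_relabel.py`).

The `examples/` directory has one short script per capability: isomiR
calling (`01`), cross-species relabeling (`02`), DE gene-set overlap with a
planted concordant/divergent design (`03`) and ΔΔCt quantification (`04`).
A thin CLI mirrors the library:

```
isomirkit simulate reads --seed 42 --out sim/
isomirkit call --reads sim/reads.fastq --hairpin sim/hairpin.fa \
               --mature sim/mature.fa --out profile.tsv
isomirkit compare --a prof_a.tsv --b prof_b.tsv --mature <id> --top 5
isomirkit overlap --ref mir.tsv --iso plusA.tsv --iso trimA.tsv
```

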