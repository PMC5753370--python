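# domarch

Assigning structural domains to a protein sequence with a library of profile
HMMs typically yields many overlapping candidate hits — several related
superfamily models matching the same region, fragments of one domain reported
as separate rows, and weak spurious matches. **domarch** resolves such scored
candidate hits into a final *domain architecture*: the subset of mutually
non-overlapping hits with maximal total score, ordered along the sequence. It
is aimed at people running `hmmsearch` against domain-family HMM libraries
(e.g. CATH-style superfamily models) who need clean per-protein domain
assignments, and at people benchmarking such pipelines.

## What it computes

Given candidate hits $h_1,\dots,h_n$ for one query, each with residue
segments $\mathrm{seg}(h_i)$ (one segment for an ordinary domain, two or more
for a *discontinuous* domain wrapped around an insertion) and a positive
score $s_i$ (the HMMER bitscore by default), the resolver solves

$$\max_{S \subseteq \{1..n\}} \sum_{i \in S} s_i
\quad\text{s.t.}\quad \mathrm{seg}(h_i) \cap \mathrm{seg}(h_j) = \emptyset
\ \ \forall\, i \ne j \in S$$

by dynamic programming over sequence positions, with the set of still-open
discontinuous hits as the DP state. A hit may sit *inside the gap* of a
discontinuous hit without clashing — the case that makes this harder than
weighted interval scheduling. An exhaustive $2^n$ oracle
(`resolve_brute_force`) is included and the DP is verified against it.

Around the resolver sit the standard pipeline pieces:

* **`hmmer_io`** — reads HMMER3 `--domtblout` tables (envelope or alignment
  coordinates) and a simple hits TSV; joins split rows of one model into
  multi-segment hits (`join_split_rows`); writes resolved architectures.
* **`resolver` filtering** — e-values rescaled linearly to a common search
  space size (`-Z`-style, default $10^7$), then a strict independent
  e-value cut (< 0.001) for the *significant* tier and a conditional
  e-value cut for an opt-in *low-confidence* tier.
* **`hmm_library`** — the iterative-search round-selection rule (keep round
  1 unless round 2 strictly improves TP or FP without hurting the other),
  construction of the contiguous region spanning a discontinuous domain for
  building insertion-aware HMMs, and per-domain TP/FP benchmarking against
  gold choppings (bidirectional 80% residue overlap + family match).
* **`synthetic`** — a seeded generator of planted domain architectures
  (including insertion events) and noisy candidate hits, so everything is
  testable end to end without external data.

Coordinates are 1-based and inclusive throughout; segment lists use the
chopping syntax `start-stop[_start-stop...]`, e.g. `1-100_201-300`.

## Worked example

```python
from domarch import DomainHit, HitSet, parse_chopping, resolve

hits = [
    DomainHit("sp|P12345", "3.20.170.30", tuple(parse_chopping("12-110_241-330")),
              bitscore=182.4, indp_evalue=3.1e-52, resolve_score=182.4),
    DomainHit("sp|P12345", "3.40.50.300", tuple(parse_chopping("118-236")),
              bitscore=95.7, indp_evalue=2.4e-25, resolve_score=95.7),
    DomainHit("sp|P12345", "1.10.510.10", tuple(parse_chopping("60-280")),
              bitscore=201.0, indp_evalue=8.8e-58, resolve_score=201.0),
]
arch = resolve(HitSet("sp|P12345", hits))
print(f"total score: {arch.total_score:.1f}")
for h in arch.selected:
    print(f"  {h.match_id:<12} {h.chopping:<15} {h.bitscore:.1f} bits")
```

prints

```
total score: 278.1
  3.20.170.30  12-110_241-330  182.4 bits
  3.40.50.300  118-236         95.7 bits
```

The single 201-bit hit spanning 60–280 loses: the discontinuous
`3.20.170.30` domain plus the `3.40.50.300` domain inserted into its gap are
compatible (no shared residue) and together score 278.1 bits.

The same pipeline from the shell, on simulated data:

```sh
$ domarch simulate --seed 11 --n-proteins 5 --out-gold gold.tsv --out-hits hits.tsv
INFO domarch: simulated 5 proteins, 18 gold domains, 26 hits
$ domarch resolve hits.tsv --trim 8 --output resolved.tsv
INFO domarch: read 26 hits; 20 significant, 1 low-confidence; selected 18 across 5 queries
$ domarch benchmark --predictions resolved.tsv --gold gold.tsv | tail -5
#summary	tp	18
#summary	fp	0
#summary	overall_pct	100.0000
#summary	discontinuous_pct	100.0000
#summary	skipped_queries	0
```

`overall_pct` is the percentage of planted gold domains recovered by a
matching prediction; `discontinuous_pct` restricts this to discontinuous
gold domains and additionally requires the prediction to reproduce the
discontinuity (≥ 2 segments). `--trim 8` lets the resolver shave marginal
boundary overlaps (≤ 8 residues) off the lower-scoring hit instead of
discarding it — see `docs/methods.md`.

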