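# Methods

## The resolution problem

A profile-HMM scan of one query protein returns candidate domain hits
$h_i$, each a set of one or more residue segments with a bitscore and two
per-domain e-values (independent and conditional). Domains must not overlap
in the final architecture, but candidates overlap freely — different
superfamily models matching the same region, or one model matching twice.
Resolution selects the subset $S$ of pairwise residue-disjoint hits
maximising $\sum_{i\in S} s_i$, where $s_i$ is the hit's `resolve_score`.

`resolve_score` defaults to the bitscore: it is additive, positive, and
independent of database size, so subsets compare meaningfully. Any positive
score can be substituted per hit (e.g. a length-normalised or
e-value-derived transform) before calling the resolver.

### Dynamic programme

Hits are sorted by first-segment start and processed left to right. The DP
state at hit $i$ is the set of already-selected hits that are still *open* —
whose last segment ends at or beyond $h_i$'s first start and which can
therefore still clash with $h_i$ or later hits. Two open continuous hits
would necessarily cover the current position and hence clash, so at most
one continuous hit is ever open; the state space is exponential only in the
number of simultaneously open *discontinuous* hits. That number is capped
at `max_inflight` (default 6, above any biologically plausible insertion
nesting depth). Within the cap the result is the global optimum — verified
against the exhaustive $2^n$ oracle on 1,000 random instances per run of
the acceptance script; beyond it the inclusion branch is pruned, a
`ResolverWarning` is emitted, and the result remains feasible (clash-free)
but may be sub-optimal.

Memoisation keys are `(hit index, frozenset of open hits)`; hits whose last
stop falls before the current first start are pruned from the key, which is
what keeps the table small.

### Ties and determinism

Equal-score optima are ordered deterministically: prefer fewer hits, then
the lexicographically smallest sorted list of `(first_start, match_id)`
pairs. The brute-force oracle applies the identical rule, so the two routes
agree on the selected subset as well as on the score. Resolution is a pure
function of (hit set, options): repeated runs are bit-identical, and
multiplying all scores by a positive constant does not change the selection.

### Overlap tolerance and trimming

By default a single shared residue is a clash. `trim = t` allows the
resolver to shave up to *t* residues off a **lower-scoring** hit's segment
*ends* when that fully clears an overlap with a higher-scoring hit; interior
overlaps and overlaps deeper than *t* are never trimmed, and a segment is
never trimmed away entirely. Trimming runs once, against hits in descending
score order, before the DP.

Trimming matters because adjacent true domains (in particular an inserted
domain flush against the arms of its discontinuous host) acquire small
mutual overlaps from envelope-boundary noise; with zero tolerance one of two
correct hits would be discarded. The noisy benchmarks use `trim = 8`:
boundary jitter is modelled per boundary with s.d. 3 residues, so the
overlap of two independently jittered adjacent boundaries has s.d.
$\sqrt{18} \approx 4.2$, and 8 residues ≈ 2 s.d. covers almost all marginal
cases while leaving genuine (deep) conflicts to the score comparison.

## Filtering

E-values scale linearly with the effective search-space size, so hits from a
scan run with one `-Z` are first rescaled by `z_target / z_current`
(default target $10^7$). Tiers are then:

* **significant** — independent e-value strictly `< indp_threshold`
  (default 0.001);
* **low confidence** — fails the independent cut but conditional e-value
  strictly `< cond_threshold` (default 0.001);
* everything else is dropped.

Filtering precedes resolution; low-confidence hits enter the resolution
pool only on explicit request (`--include-low-confidence`). Thresholds are
strict inequalities, so a hit at exactly 0.001 fails.

## HMM-library procedures

**Round selection.** When a family HMM is refined by iterated search, the
round-1 profile is kept by default; the round-2 profile replaces it iff, on
a gold-standard benchmark, true positives increase with no increase in false
positives, or false positives decrease with no decrease in true positives.
The rule is a total function of the two `(tp, fp)` pairs and is tested by
exhaustive enumeration.

**Discontinuous regions.** For a discontinuous gold domain, the region from
its first start to its last stop — the domain *plus* everything inserted
into it — is the sequence from which an insertion-aware HMM is built, since
host and insert behave as an evolutionarily stable unit after the insertion
event. `build_discontinuous_region` returns exactly that span and refuses
continuous input.

**Benchmarking.** Counting is per-domain. A prediction is a true positive
when an unconsumed gold annotation shares at least `min_overlap_fraction`
(default 0.8) of **both** the prediction's and the gold's covered residues,
with equal family ids unless disabled. Matching is greedy by descending
prediction score and one-to-one (each gold consumed at most once), so
`tp + fp` equals the number of predictions and `tp` never exceeds the
number of golds. `discontinuous_accuracy` is the percentage of discontinuous
gold domains whose matched prediction itself has ≥ 2 segments — a
continuous prediction spanning the whole region does not count, because it
misassigns the inserted domain's residues.

The 0.8 bidirectional criterion is a deliberate middle ground: loose enough
to absorb envelope jitter of a few residues on domains ≥ 50 residues, tight
enough that a prediction covering half a domain (or double it) fails.

## Synthetic data

The generator plants, per protein (length uniform in 250–800 residues),
a left-to-right architecture of domains (lengths uniform in 50–200) with
5–25-residue linkers. With probability `insertion_prob` (default 0.25) a
domain becomes a discontinuous host: it is split into two arms of ≥ 20
residues each and an independently drawn inner domain is planted flush in
the gap. Family identifiers are drawn without replacement per protein from
a fixed pool of 72 superfamily-style codes.

Hits are then emitted per gold domain with each boundary jittered by
rounded $\mathcal N(0, \sigma^2)$ (default $\sigma = 3$ residues) and a
bitscore drawn from $\mathcal N(80, 15^2)$ truncated below at 40 bits —
planted domains model *confidently detectable* homology, kept above the
~33 bits at which the default e-value cut bites, so recovery benchmarks
measure resolution rather than filter misses. Decoy hits arrive at
Poisson rate `decoy_rate` (default 2 per protein) at uniform positions with
bitscores $\mathcal N(25, 8^2)$; roughly the top sixth of decoys clears the
significance cut, which is what keeps the filter and resolver both
exercised. E-values follow the exponential-tail map
$E = Z\,2^{-\text{bits}}$ (floored at $10^{-300}$), with the conditional
e-value fixed at $E/50$.

By default a discontinuous gold domain yields one multi-segment hit, as an
insertion-aware HMM would produce. With `split_discontinuous=True` it
yields one single-segment hit per arm with the bitscore split pro rata —
emulating a standard single-domain HMM whose envelope breaks across the
insertion. Comparing resolution with and without `join_split_rows` on such
data quantifies the benefit of multi-segment handling; the claim asserted
is directional (joining strictly increases discontinuous accuracy), not a
particular magnitude.

Randomness is hierarchical: protein *i* uses sub-streams keyed
`(seed, i, phase)` with truth and hit noise in separate phases and true-hit
draws preceding decoy draws, so outputs are byte-identical for identical
configs, protein *i* is unchanged when `n_proteins` changes, and changing
the decoy rate leaves true hits untouched.

What the simulator does **not** model: actual amino-acid sequences and HMM
emission, correlated boundary errors, partial/fragmented true hits,
homologous decoys overlapping true domains in the *same* family, or
nested discontinuity deeper than one level. Passing recovery benchmarks
therefore demonstrates correctness of filtering + resolution under
idealised scan statistics, not end-to-end annotation accuracy on real
proteomes.

## Problem sizes and numerical choices

The standard benchmark sizes are 1,000 random hit sets (≤ 12 hits, ≤ 3
segments) for the DP/oracle comparison, 200 proteins for the recovery
benchmarks, 100 proteins (insertion probability 0.5) for the discontinuous
comparison, and 10,000 instances for format round trips; each runs in
seconds and together they keep the full suite near interactive speed while
estimating percentages to ~1 point. Score sums are compared at relative
tolerance $10^{-9}$ (float addition order differs between the DP and the
oracle). The architecture container validates disjointness, ordering and
the score total on construction, so feasibility is asserted on every output
everywhere, not just in tests.

## Known limitations

* Beyond `max_inflight` simultaneously open discontinuous hits the result
  is only guaranteed feasible; real architectures never approach the
  default cap of 6.
* `join_split_rows` merges by (query, model) and gap size only; two genuine
  adjacent copies of the same family separated by less than `max_gap`
  would be spuriously merged (joining is therefore opt-in).
* Trimming is greedy in score order and not revisited by the DP; a
  globally better trim assignment can exist in contrived cases.
* E-value tier semantics assume the input e-values came from one scan with
  a single, known `-Z`.
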