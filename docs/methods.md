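# Methods

## Instability model

Three mutational channels are scored, all as per-generation rates in
*E. coli*-calibrated units.

**Base-pair substitution (BPS).** A uniform background of
μ_BPS = 2.2 × 10⁻¹⁰ substitutions per base per generation, the consensus
value from whole-genome sequencing of *E. coli* mutation-accumulation
lines. A sequence of length n therefore carries a baseline rate of
n·μ_BPS; this is the denominator of the RIP score.

**Simple-sequence-repeat slippage.** A tandem run of a unit of length L
(1 ≤ L ≤ 15) with N full copies qualifies as a slippage hotspot at
(N ≥ 3, L ≥ 2) or (N ≥ 4, L = 1). Slippage rates grow roughly
exponentially with copy number, so the model is log-linear:
log₁₀ μ = intercept + slope · N, with separate coefficient sets for
homopolymers (default intercept −12.91, slope 0.729 — about a five-fold
gain per added base, crossing the BPS baseline near the N = 4
qualification threshold) and multimeric units (default −10.18, 0.387 —
a shallower gain from a higher floor at N = 3). The published constants
this model is anchored to are the qualification thresholds and the
log-linear form; the two coefficient pairs are this package's own
calibration, chosen to reproduce the typical orders of magnitude of
slippage measurements in enteric bacteria, and both are overridable
through a plain `key = value` config file (`RateModel.from_config`).
Because ranking, not absolute prediction, drives the optimizer, the
choice affects reported rates but not which sites are repaired.

**Repeat-mediated deletion.** Two identical same-strand repeats of
length L ≥ 16 separated by a spacer of L_s ≥ 0 nt recombine at

    μ = μ_max · exp(−L_s / B) / (1 + exp((α − L) / A))

with A = 5.8 nt, B = 1465.6 nt, α = 29.0 nt. The logistic captures the
known sigmoidal dependence of recombination on homology length (midpoint
α, width A); the exponential captures decay with distance between the
copies (scale B). μ_max = 1 × 10⁻⁴ per generation anchors the plateau at
the deletion frequencies reported for long adjacent repeats on plasmids;
like the SSR coefficients it is a package calibration, overridable, and
irrelevant to ranking *between* RMD sites (the ratio of two RMD rates
does not depend on it). Inverted (reverse-complement) repeats are not
scored: the modelled mechanism acts on direct repeats. Copies that would
overlap are not reported.

**RIP.** RIP = (n·μ_BPS + Σ μ_SSR + Σ μ_RMD)/(n·μ_BPS) ≥ 1, with
equality exactly when no site qualifies. The whole-sequence BPS rate is
used in the denominator because that is the only normalization under
which the no-hotspot minimum is exactly 1.

## Detection

SSRs: for each unit length L the sequence is scanned for maximal runs of
period-L self matches; a run of m matches spans m + L nt and holds
⌊(m+L)/L⌋ full copies. Runs are reported once, at their leftmost start,
with the smallest primitive unit (AAAAAA is one L = 1, N = 6 site, never
also L = 2, N = 3; the trailing base of ATATATA is not part of the run).
RMDs: all 16-mers are hash-indexed; every pair of occurrences of a shared
16-mer seeds a maximal extension at its offset, which merges consecutive
shared 16-mers into one repeat and emits one site per ordered copy pair
(each pair is an independent recombination opportunity). `N` bases match
nothing, including each other, and so terminate both runs and repeats.
Both detectors are verified, exactly and set-wise, against deliberately
independent brute-force enumerators (`seqstab.oracles`): an exhaustive
(start, L) tandem scan and an all-offsets self-alignment scan.

Motif scanning converts MEME-minimal position probability matrices to
log₂-odds scores, score[i][b] = log₂((ppm[i][b] + ε)/(bg[b] + ε)) with
pseudocount ε = 10⁻⁶ (curated PPMs contain exact zeros; the pseudocount
avoids −∞ without materially moving ranks). When the motif file has no
background line a uniform background is assumed. Both strands are
scanned; at each start index only the best-scoring (motif, strand) is
kept, and only if its score exceeds 0 — i.e. the site is more likely
under the motif model than under background. With a uniform prior over
candidate sites this score ordering equals the posterior ordering, which
is all the ranking needs; no methylation strength is estimated. `N`
bases contribute exactly 0 (the background expectation).

Ranking takes the top 10 sites of each type by rate/score (ties broken
by leftmost start). The budget of 10 per type bounds the optimizer's
workload while covering the sites that dominate the total rate, which is
heavily concentrated in the top few.

## Optimization

Pass 1 assigns codons per ORF — the family's most frequent codon
(`use_best_codon`); a largest-remainder allocation matching the host's
within-family frequencies that keeps current codons wherever the quota
allows, so an already-matching ORF is a fixed point
(`match_codon_usage`); or a within-family frequency-rank map from a
source table, defaulting to *E. coli* (`harmonize_rca`) — and then
drives every non-overlapping 50-nt window's GC fraction into the
configured bounds, preferring the moves that cost least codon
optimality. The `match_codon_usage` objective is reported as a negative
family-weighted L1 distance between observed and host within-family
frequencies. With no organism configured only the constraints are
resolved.

Pass 2 turns the ranked sites into pattern constraints: every 15-mer of
a repeat pair's first copy must change (so no 16-mer identity can
survive anywhere inside it), a motif hit must stop scoring above
background at its locus, and alternating unit copies (2nd, 4th, …) of a
tandem run are substituted to break slippage-prone identity. Resolution
is a deterministic, localized satisficer: synonymous codon substitutions
inside ORFs, free base substitution outside them, never in locked
regions, and no edit where no constraint demands one. Candidate edits
are screened so they do not themselves seed a new tandem run whenever a
clean alternative exists, and when the greedy/alternating primitives
plateau (e.g. a lysine stretch whose AAA/AAG choices each leave some
periodic pattern) a seeded search over joint assignments of the editable
choice points in the neighbourhood takes over. Constraint resolution, a
cleanup sweep that re-detects and repairs mutational hotspots the edits
introduced, and guarded GC-window restoration run to a joint fixed point
(bounded rounds). A constraint with no legal solution — a site inside a
locked region, or one whose every covering codon is synonym-free — is
reported as unsatisfied, never silently dropped. The whole pass is a
pure function of (sequence, spec, seed).

An independent audit (`verify_result`) re-checks every promise with
separate code paths — Biopython's translator for ORFs, byte comparison
for locks, direct window counts for GC, re-detection for targeted sites,
and a Hamming recount of the change log — and raises on any violation.

The "zero new hotspots" guarantee the cleanup sweep aims for is enforced
for the mutational classes (SSR/RMD). New *motif* hits are not chased to
zero: on random background a PSSM hit with score barely above 0 is
commonplace, so demanding their absence would force unbounded rewriting
for negligible epigenetic benefit; targeted motif sites are removed,
incidental sub-threshold ones are reported in the site tables.

## Synthetic data

The fixture generator produces what the detectors and optimizer are
specified against, not what real constructs look like:

* `random_sequence(length, gc, seed)` — iid background with the G+C count
  fixed exactly (positions shuffled), so composition targets hold by
  construction rather than binomially.
* `hotspot_free_sequence` — random background repaired until the
  *exhaustive* enumerators certify no qualifying SSR and no duplicated
  16-mer. This is the RIP = 1 reference state.
* `plant_ssr` / `plant_rmd` / `plant_motif` — exact substring placement
  with single-base flank repair so the maximal extent a detector should
  report equals the declared extent; planted features may not overlap.
* `random_orf` — codon-wise encoding of an amino-acid string, guaranteeing
  frame, no internal stop, and a terminal stop.

The optimizer repair fixtures (1.5-kb backgrounds, one ~330-codon ORF
carrying a 9-nt lysine homopolymer and a duplicated 21-nt codon block,
GC bounds 0.30–0.70, one 50-nt locked prefix) avoid tryptophan and
same-residue adjacency in the random protein, because Trp/Met codons
have no synonyms and residue doubling can make a planted run provably
unremovable (a four-lysine run already is: every Lys codon starts AA).
Passing these suites therefore shows the machinery honours its contracts
where a solution exists and reports honestly where none does; it does
not show that arbitrary natural ORFs are always fully repairable — they
are not, and the unsatisfied-constraint report is the designed outcome
for such loci. Real sequences also carry correlated composition,
regulatory elements and repeat families that iid backgrounds do not
emulate.

Problem sizes used by the shipped verification suites — 200 random
kilobases for detector/oracle parity, 100 planted-recovery fixtures, 50
end-to-end repair fixtures, 10-kb clean sequences for the RIP minimum —
were chosen so each suite pins down its property with comfortable margin
at interactive runtimes.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally, 1-based inclusive in all
  CSV/report output (stated in the CSV headers).
* GC windows are non-overlapping, anchored at 0; the final short window
  is checked at its actual length. Window bounds are compared with a
  1e-12 slack so fractions like 0.3 are not lost to float noise.
* Empty sequences: detection returns empty lists; RIP is undefined
  (error) at length 0.
* Ambiguity codes other than N are rejected at ingestion — substitution
  semantics for them are undefined. U is converted to T with a warning.
* Ties in ranking break by leftmost start; ties among equally good codon
  candidates break alphabetically, keeping every pipeline stage
  deterministic. Default seed 0, echoed into every run manifest.
* Stop codons inside an ORF (other than terminal) are an error; terminal
  stops may swap among synonymous stops, since the embedded usage tables
  cover the stop family.
* Codon-usage tables are embedded approximations of genomic usage for
  the nine supported hosts, renormalised per synonymous family at load
  so family frequencies sum to 1 exactly; codon choice needs the
  preference ranking, not database-precision decimals.

## Known limitations

* Absolute rates are *E. coli* calibrations; for other hosts only the
  ranking of sites is meaningful, a caveat recorded in the run manifest.
* RMD scoring treats copy pairs independently; no attempt is made to
  model interference among three or more copies of the same repeat.
* The optimizer is a satisficer, not an exact solver: it guarantees its
  hard constraints and reports what it could not do, but does not prove
  optimality of the codon objective after repair.
* Motif scanning reports likelihood-ratio scores, not methylation
  probabilities or strengths.
* GenBank output uses one feature per changed position; graphical
  sequence icons are replaced by a deterministic hash token.
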