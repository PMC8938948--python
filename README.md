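# seqstab

Evolutionary-stability analysis and repair of synthetic DNA constructs.

Engineered sequences impose a fitness cost on their host, so any mutation
that silences the construct tends to sweep through the culture. Most of
those mutations do not arrive uniformly along the sequence: they cluster
at **mutational hotspots** — simple sequence repeats (SSRs), where a short
unit repeated in tandem invites polymerase slippage, and long direct
repeats (≥ 16 nt), which mediate repeat-mediated deletion (RMD) of
everything between the two copies — and at **epigenetic hotspots**,
methylation-prone motifs that silence transgenes in mammalian and insect
hosts. `seqstab` finds all three classes in batches of FASTA/GenBank
files, ranks them by predicted per-generation mutation rate, and rewrites
the sequence to remove the worst offenders while preserving the protein,
locked regions, windowed GC bounds and host codon-usage preferences.

## The model

Per-generation rates are calibrated on *E. coli* mutation-accumulation
data; for other hosts the ranking of sites is meaningful, the absolute
values are not.

* **BPS** (base-pair substitution) baseline: μ_BPS = 2.2 × 10⁻¹⁰ per base
  per generation; a sequence of length n drifts at n·μ_BPS.
* **SSR slippage** for a run of unit length L with N copies (qualifying at
  N ≥ 3 for L ≥ 2, N ≥ 4 for L = 1): log₁₀ μ is affine in N, with separate
  fitted coefficients for homopolymers and multimeric units.
* **RMD recombination** for two identical direct repeats of length L
  separated by L_s nt:
  μ = μ_max · exp(−L_s / B) / (1 + exp((α − L) / A)), a logistic in repeat
  length (midpoint α = 29.0 nt, width A = 5.8 nt) with exponential spacer
  decay (B = 1465.6 nt).
* **RIP score** (Relative Instability Prediction):
  RIP = (BPS + Σ μ_SSR + Σ μ_RMD) / BPS — "how much more likely is this
  sequence to mutate than an equally long clean one?" Its minimum, exactly
  1, is attained iff no hotspot is present.
* **Methylation/custom motifs** come as position probability matrices in
  MEME minimal format, are converted to log₂-odds PSSMs against background
  frequencies, and both strands are scanned; only sites scoring above
  background (score > 0) are kept and ranked.

The optimizer runs two passes: pass 1 codon-optimizes every ORF
(`use_best_codon`, `match_codon_usage` or `harmonize_rca`) and regulates
GC content in non-overlapping 50-nt windows; pass 2 re-detects hotspots on
the semi-optimized sequence and removes the top 10 of each type by
synonymous substitution inside ORFs and free substitution outside them,
never touching locked regions. Working on an already-optimal sequence
means hotspot repair rarely spawns new problematic sites; a bounded
cleanup sweep removes any that do appear.

## Worked example

```python
from seqstab import (
    OptimizationSpec, derive_avoid_constraints, find_rmd_sites, find_ssr_sites,
    first_pass, hotspot_free_sequence, plant_rmd, plant_ssr, rank_sites,
    rip_score, second_pass,
)

background = hotspot_free_sequence(1000, seed=7)
seq, _ = plant_ssr(background, "CA", 5, 120)       # (CA)x5 slippage site
seq, _ = plant_rmd(seq, 20, 40, 500)               # 20-nt direct repeat, 40-nt spacer

ssr, rmd = find_ssr_sites(seq), find_rmd_sites(seq)
for site in ssr:
    print(f"SSR  unit={site.unit} N={site.n_copies} span=[{site.start},{site.end}) "
          f"rate={site.rate:.2e}/generation")
for site in rmd:
    print(f"RMD  L={site.repeat_len} spacer={site.spacer} copies at "
          f"{site.first_start} and {site.second_start} rate={site.rate:.2e}/generation")
print(f"RIP before: {rip_score(len(seq), ssr, rmd):.2f}")

spec = OptimizationSpec(gc_min=0.3, gc_max=0.7, seed=0)
semi = first_pass(seq, spec)
constraints, skipped = derive_avoid_constraints(rank_sites(ssr, 10) + rank_sites(rmd, 10))
result = second_pass(semi, spec, constraints, skipped)
out = result.sequence
print(f"changes: {len(result.changes)}  removed: {result.removed}")
print(f"RIP after: {rip_score(len(out), find_ssr_sites(out), find_rmd_sites(out)):.2f}")
```

prints

```
SSR  unit=CA N=5 span=[120,130) rate=5.69e-09/generation
RMD  L=20 spacer=40 copies at 500 and 560 rate=1.70e-05/generation
RIP before: 78.36
changes: 3  removed: {'ssr': 1, 'rmd': 1, 'motif': 0}
RIP after: 1.00
```

The planted repeat pair dominates the instability — a 20-nt repeat recombines
about 3000× faster than the (CA)₅ run slips — and three substitutions
(one in every other CA copy, one per 15-mer window of the repeat's first
copy) bring the sequence back to the theoretical minimum RIP of 1.

## Command line

```bash
seqstab --input-dir constructs/ --output-dir results/ \
        --organism "E. coli" --method use_best_codon \
        --gc-min 0.3 --gc-max 0.7 \
        --orf 1:101-703 --lock 1:1-50 \
        --motifs methylation --format both --seed 0
```

Every FASTA/GenBank file under `constructs/` (gzip/zip accepted) is
analyzed; the output tree mirrors the input tree, one folder per input
file with per-type site CSVs (1-based inclusive coordinates), optimized
sequences, a change summary, and a zip bundle with the final GenBank,
report and a deterministic sequence-identicon token. `--report-only`
skips optimization and just lists the sites. ORF and locked spans are
given per sequence number (`SEQNUM:START-END`, 1-based inclusive).

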