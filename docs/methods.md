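# Methods

`lncorf` implements a three-stage analysis of de novo protein-coding
gene origination from long non-coding RNA (lncRNA) precursors —
*emergence*, *retention*, *selection* — together with a synthetic-data
generator that reproduces the statistical structure each stage assumes.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not emulate.

## Emergence: ORF dating and common ancestral disablers

A candidate de novo gene is a human ORF whose orthologous region in
outgroup species does not encode the protein. Each outgroup is scored
through a codon-level pairwise alignment to the human CDS:

* **Alignment quality gate.** Coverage > 0.7 and identity > 0.5, both
  strict. Boundary values fail; an outgroup without a passing alignment
  contributes no evidence.
* **Disruptions.** A subject codon that is a stop codon (premature
  stop), or an indel whose length is not a multiple of 3 (frameshift).
  In-frame indels are not disruptions. Rows aligned to the query's
  terminal stop codon are outside the ORF proper and are ignored.
* **ORF absence rule.** The longest run of consecutively aligned query
  codons between disruptions (disrupted codons excluded; unaligned gaps
  break runs) is divided by the human ORF length in sense codons. The
  ORF is absent when a disruption exists and this fraction is < 0.7
  (strict, matching the "shorter than 70%" reading).
* **Common ancestral disabler.** A disruption with identical kind at the
  same query-codon position in *every* ORF-absent outgroup, requiring at
  least two absent outgroups. Query (human) codon coordinates are the
  only frame shared across outgroups, so "same position" is defined
  there. A shared disabler implies the disruption predates the outgroup
  radiation and was resolved on the human lineage — a newly originated
  gene; independent disablers at different positions indicate an old
  gene dying in parallel, and such genes are excluded.
* **Age assignment.** Dollo parsimony on a dated species tree
  (((((human, chimp), gorilla), orangutan), macaque), mouse): one gain
  at the most recent common ancestor of all ORF-present species, losses
  for absent species inside that clade. When an independent-gains
  scenario costs no more events than the Dollo scenario the assignment
  is flagged ambiguous (such genes are excluded from age-specific
  summaries but still reported). Two labels are emitted: the
  origin-clade label (H, H-C, H-C-G, H-C-G-O, pre-hominoid) and the
  present-species list (e.g. "H-C-O" when the gorilla ORF is absent or
  unsampled), because published catalogs use the latter.
* **Divergence dN/dS.** Nei–Gojobori (1986) counting, pooled across
  genes before the Jukes–Cantor correction: fractional
  synonymous/nonsynonymous site counts are averaged over the two
  sequences of each aligned codon pair, observed differences are
  averaged over all mutational pathways, and codon pairs containing a
  stop codon are excluded (a premature stop is a disruption, not
  divergence). The conventions match `Bio.codonalign`'s NG86
  implementation, which the test suite uses as an independent
  cross-check. Pooling before correcting stabilizes the estimate for
  short ORFs with few differences.

## Retention: GC, fragile codons, and neutral ORF lifespan

The three stop codons (TAA, TAG, TGA) are AT-rich, so GC-rich ORFs are
less exposed to nonsense mutations. Two sequence statistics quantify
this: GC content (N bases excluded from numerator and denominator; GC3
restricted to third positions of sense codons) and the fragile-codon
fraction — the proportion of sense codons one point mutation away from a
stop (18 of the 61 sense codons in the standard code). A codon counts
once even if it neighbours two stops; the weighted count (number of
stop-creating single-base changes) is exposed separately as
`stop_mutation_opportunities` because it is the quantity that enters the
nonsense-mutation hazard.

**Lifespan simulation.** An unconstrained ORF is eventually interrupted
by a premature stop or a frameshift. The simulator is event-driven:
waiting times between mutation events are exponential with total rate
`L·(μ+ν)` (`L` = current length in nucleotides, terminal stop included),
each event picks a site uniformly; a point event substitutes one of the
three alternative bases (transition weight κ, default 1 = uniform) and
updates the sequence; an indel event interrupts immediately when its
length is not a multiple of 3 (default: fixed length 1, always
frameshifting; a geometric-length mode with mean 3 exists but is off by
default). Interruption is declared when any internal codon becomes a
stop or a frameshifting indel lands anywhere in the ORF; loss of the
terminal stop codon does not count, mirroring the disruption definition
used for ortholog assessment. Defaults: μ = 1.25×10⁻⁹ and ν = 0.1×10⁻⁹
per site per year; horizon 10¹⁰ years with censoring (the censored
fraction is reported, and the half-life is undefined when it reaches
0.5).

The half-life t½ is the median interruption time over 20,000 replicates
(configurable, minimum 100). Because fragile codons mutate away faster
than they are created in typical sequences, the hazard decays over time
and the median sits *above* the constant-hazard first-event
approximation ln2/(ν·L + μ/3·k): for the 3-codon toy ORF ATG-TGG-TAA
the exact median (computable by matrix exponentials, since internal
codons evolve as independent killed Markov chains) is 15.4% larger.
The test suite checks the simulator against that exact computation and
against an independent discrete-time re-implementation.

**Survival probability.** Given a lineage age T (years since the
relevant species divergence), λ = (1/2)^(T/t½) and p = λ·e^(−λ). The
formula is implemented verbatim; note it yields p = e⁻¹ ≈ 0.368 at
T = 0, which is why it is described as a *minimal* probability, and we
do not reinterpret it. Divergence times are configuration inputs keyed
by age label (defaults: H 6 Myr, H-C 8 Myr, H-C-G 14 Myr, H-C-G-O
25 Myr).

## Expression evidence

RPKM = reads·10⁹/(library size · region length), computed from supplied
count tables (read mapping is out of scope). Transcription calls compare
against an empirical background of 10,000 intergenic regions with the
(k+1)/(N+1) pseudo-count; a gene is called expressed when its maximum
tissue RPKM strictly exceeds 0.5 (ortholog transcription uses 0.2), so
boundary ties fail. Relative expression is genic RPKM over the sum with
equal-length upstream/downstream flanks; junction support defaults to
≥1 spliced read (configurable); tissue-profile similarity uses Spearman
correlation with mid-ranked ties. Mass-spectrometry peptide evidence is
consumed as a per-gene boolean input, never computed.

## Selection: population-genetics contrasts

* π uses the unbiased per-site heterozygosity 2p(1−p)·n/(n−1) summed
  over segregating sites and divided by surveyed length; θw = S/(aₙ·L)
  with aₙ the harmonic number. Sites with missing genotypes contribute
  with their own site-specific n.
* Site classification locates the codon through the spliced CDS in
  coding order (strand-aware; minus-strand alleles are complemented).
  *Pseudo*-synonymous/nonsynonymous sites on non-coding orthologs are
  classified by mapping the position through the codon alignment into
  the query reading frame and mutating the subject codon. Stop-creating
  variants are nonsynonymous with a nonsense sub-flag; sites whose
  reference allele disagrees with the supplied sequence, or that fall in
  insertions/partially deleted codons, are flagged unclassifiable rather
  than dropped silently.
* πN/πS uses NG86 fractional site counts of the reference CDS as
  denominators, so the neutral expectation of the ratio is 1. πS = 0
  flags the ratio undefined.
* Unfolded spectra pool sites across genes (per-gene averaging is the
  rejected alternative); unpolarizable sites (ancestral allele matching
  neither observed allele) are excluded and counted. Sites with more
  chromosomes than the target n are projected down by the hypergeometric
  expectation, with mass landing on monomorphic classes discarded; sites
  with fewer are skipped. Bootstrap CIs resample sites with replacement
  (B = 1000 by default; 2.5/97.5 percentiles and per-bin SD reported).
* The rare-variant excess test is a one-sided two-proportion z-test on
  the lowest-frequency class; identical spectra give p = 0.5 exactly.
* The exon/intron Monte Carlo test places the observed exonic+intronic
  variant count k independently with P(exon) = exon length/(exon+intron
  length) (10,000 simulations by default) and reports the lower-tail
  (k+1)/(N+1)-corrected p. Exon length is the union of CDS, UTR and
  explicit exon intervals; stored region classes must be disjoint.

## Synthetic data: what it emulates, and what it does not

* **Sequences.** I.i.d. bases at a target GC; ORF mode forces ATG,
  resamples internal stops and ends with a composition-weighted stop.
  Generated GC is within ±0.02 of target from ~3 kb.
* **Ortholog panels.** The ancestor ORF evolves down the dated tree
  with Poisson numbers of point substitutions per branch
  (μ·years·length). The tree's branch lengths are in years (human–chimp
  split 6 Myr through mouse 90 Myr). Indels enter only as injected
  disablers, so true codon alignments are emitted alongside. A
  *de novo* scenario injects the disabler into the root sequence and
  reverts it on the human terminal branch — all outgroups share it at
  the same aligned position; a *dying* decoy injects independent
  disablers on outgroup terminal branches at distinct positions;
  *controls* evolve with nonsense substitutions rejected on every
  branch, emulating long-term coding constraint.
  Two ascertainment conditions are built in, because the real catalog is
  conditioned on what is observable today: nonsense substitutions are
  rejected along the human path (the human ORF is intact now, including
  its terminal stop), and injected-disabler codons are protected from
  further substitution (the catalog only contains genes whose shared
  disabler is still detectable). Without the latter, roughly a quarter
  of deep-branch simulations would erase the shared signature.
* **Polymorphism.** Derived-allele counts are drawn from the
  Wright–Fisher diffusion expectation under genic selection:
  E[ξᵢ;γ] ∝ ∫₀¹ C(n,i)qⁱ(1−q)ⁿ⁻ⁱ·f(q;γ)dq with sojourn density
  f(q;γ) = (1−e^(−2γ(1−q)))/((1−e^(−2γ))·q(1−q)), which reduces to the
  neutral 1/i law as γ→0 (integrals by adaptive quadrature, cached per
  (n,γ)). Selection also thins the number of segregating sites: each
  class realizes Poisson(budget × Σᵢwᵢ(γ)/Σᵢwᵢ(0)). Site positions are
  drawn without replacement from the class's actual mutational
  opportunities in the CDS (so classification round-trips exactly), one
  variant per position; the ancestral allele is written as the reference
  so spectra are unfolded by construction. Default panel: 1600-codon
  CDS, 6 kb intron, neutral density 0.35 segregating sites per NG86
  site, n = 134 chromosomes (67 diploid individuals), γ = −10 on
  nonsynonymous sites for the selected ("human-like") panel and γ = 0
  everywhere for the neutral ("macaque-like") panel.
* **Expression.** Log-normal tissue profiles, median ≈ 1.2 RPKM with
  σ_log = 0.8 — the low-abundance regime typical of de novo genes
  (reliably above the 0.5 call cutoff in at least one of 17 tissues,
  far below abundant mRNAs) — shared across species plus independent
  per-species noise. The intergenic background is exponential with the
  scale set so P(RPKM > 0.2) ≈ 0.02.
* **Not emulated:** linkage disequilibrium and demography (sites are
  independent), CpG hypermutability and rate heterogeneity, real indel
  length spectra in ortholog evolution, read-level noise, and
  mass-spectrometry evidence. Passing tests therefore demonstrate that
  the statistics recover the generative signals they are designed for,
  not that the pipeline is robust to every artefact of real sequencing
  data.

## Numerical and design choices

* All coordinates are 0-based half-open internally; VCF positions are
  converted at the boundary. Multi-allelic records are decomposed into
  biallelic records (genotypes carrying a third allele become missing);
  missing genotypes reduce the site-specific chromosome count.
* Monte Carlo and empirical p-values use the (k+1)/(N+1) estimator so
  p is never 0.
* Every stochastic routine takes an explicit seed; identical seeds give
  bit-identical output (including written VCF bytes).
* Problem sizes in the test suite (e.g. 50-replicate selection
  recovery, 100-bundle end-to-end classification, 20,000-replicate
  lifespan runs only where the contract names that number) were chosen
  to give stable verdicts on a single CPU; the acceptance script uses
  20 replicates per aggregate for the same reason.

## Known limitations

* The common-disabler rule requires ≥2 ORF-absent outgroups; genes with
  a single informative outgroup are reported as insufficient evidence.
* Dollo parsimony ties are flagged, not resolved; the "H-C-O" style
  labels deliberately preserve the distinction between clade of origin
  and species observed.
* The lifespan simulator models point substitutions and single-base (or
  geometric-length) indels only; selection during the simulation is out
  of scope by design.
* πN/πS for loci with zero synonymous diversity is undefined and
  reported as such rather than imputed.
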