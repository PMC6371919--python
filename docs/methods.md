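# Methods

## Spike-in calibrated ChIP at desk scale

### What the pipeline computes

Reads from a mixed-species ChIP sample are assigned to exactly one genome by
sequential alignment: first against the calibration (spike-in) genome, with
only the *unaligned* leftovers tested against the experimental genome, and
only unique hits accepted. The four uniquely-assigned counts — WCE and IP
reads on the experimental (x) and calibration (c) genomes — give the
occupancy ratio

    OR = (W_c · IP_x) / (W_x · IP_c),

the factor by which the IP enriched experimental chromatin relative to the
spike-in, normalized by the mixing proportions observed in the whole-cell
extract. Coverage is a zero-filled per-base depth vector (every position
present, gaps at 0; mpileup semantics, i.e. "number of reads at each base
pair" counts reads *covering* a base, not read starts). The meta-profile
averages depth across chromosomes at integer offsets within ±W of a
per-chromosome anchor (default W = 60 000 bp, the window used around
centromeric CDEIII elements). Calibration multiplies raw values by
OR × 10⁶ / IP_x. Because both factors are multiplicative, the order
(average, then OR, then per-million) does not affect the result.

Decisions where the procedure was genuinely open:

- **Per-million denominator.** Uniquely assigned experimental-genome IP
  reads (IP_x) by default; `occupancy_ratio(..., denominator="ip_all")`
  uses IP_x + IP_c instead. Both are exposed because the convention is not
  forced by the formula; only the default is asserted in tests.
- **Window truncation.** A chromosome whose anchor sits closer than W to an
  end contributes only its in-bounds offsets ("up to 60 kb" read as
  permitting truncation); offsets covered by no chromosome are NaN with
  `n_contributing = 0`, never zero-padded.
- **Multi-mapping reads in the calibration pass.** A read matching the
  calibration genome at more than one locus is consumed there (unassigned)
  rather than retried against the experimental genome, mirroring sequential
  alignment in which a multi-mapping read still aligns and therefore never
  reaches the second aligner's input.
- **Uniqueness surrogate.** The desk-scale mapper is exact-match over both
  strands; "unique" means exactly one hit across both strands. Production
  pipelines express the same intent through aligner mapping quality, so the
  SAM ingest path treats records below a configurable MAPQ floor
  (default 10) as unassigned. The floor is a documented default, not a
  claimed community standard.
- **Coordinates.** 1-based inclusive internally; SAM POS adopted unchanged;
  BED and bedGraph output convert to 0-based half-open. Reverse-strand
  matches are reported at the leftmost base on the forward strand.
- **Text tracks.** bedGraph (run-length-collapsed) and fixedStep wiggle are
  emitted as plain text; values are formatted so that a parse round-trip
  reproduces the depth vector bit-exactly. Binary BigWig is deliberately
  out of scope.

### What the simulator emulates — and what it does not

`make_toy_genome_pair` draws uniform-random A/C/G/T sequences and resamples
until every read-length-mer is unique across both strands of both genomes
(bounded retries, then a "genome too repetitive" error — e.g. for 1-mers,
which can never be unique). Uniqueness is a *substitute* for real genome
divergence: it guarantees unambiguous exact mapping so that assignment
accuracy is a property of the algorithm, not of sequence content.
Anchors default to chromosome midpoints. Chromosomes are capped at 200 kb.

`simulate_chip_experiment` draws WCE read starts uniformly with per-genome
weight proportional to cell ratio × genome length (default 3:1,
experimental:calibration, matching the 15:5 OD₆₀₀ mixing ratio of the
motivating protocol). IP starts on the experimental genome are drawn with
weight proportional to an anchor-centered profile: background 1.0,
peak enrichment E at the anchor, decaying *linearly* to background over
`decay_span` (default 30 000 bp, from the observed spread of
centromere-loaded cohesin up to 30 kb into peri-centric sequence; the
functional form is a modeling choice — no form is prescribed). The
calibration genome's IP signal is uniform at background level, an explicit
assumption since the spike-in's own IP structure is not modeled.

Reads are error-free, single-end, fixed 50 bp (short reads keep toy genomes
small), with uniform 'I' qualities. No sequencing error, paired ends, PCR
duplicates, mappability structure, GC bias or chromatin fragment-size
modeling — so passing tests demonstrate correctness of the *arithmetic and
contracts*, not robustness to real-data artifacts. All simulators are
deterministic given a seed.

### Problem sizes

The test suite runs the full pipeline at up to 4 × 120 kb experimental
chromosomes, 2 × 50 kb calibration chromosomes, 100k IP + 50k WCE reads —
sizes chosen so that anchor and flank depth estimates have ≈2–3% sampling
error, comfortably inside the 15% recovery tolerance, while the whole suite
stays interactive. Randomized brute-force comparisons (pileup,
meta-profile) use ≤2 kb chromosomes where exhaustive recomputation is
trivial.

## Ring-stoichiometry model

A copy's full-circularization probability is Π eᵢ over its cysteine-paired
interfaces if all three are paired (6C), else 0 (5C). For a model with copy
pool C, tagged subset T, and k rings per cohesive unit:

    CM_detectable = p_CM · c̄_T            (mean circ. fraction of tagged copies)
    CD_detectable = p_CD · c̄_T · m^(k−1)  (m = pool-mean circ. fraction)

Assumptions, stated explicitly:

- **Uniform partner draws with replacement.** Partner rings are drawn
  uniformly from the expressed pool. This is the upper-bound ("one quarter
  *or less*") case; preferential 6C–6C pairing would give smaller test-design
  CD fractions. Only the uniform case is asserted.
- **Any-member tagging suffices for IP**; detection of a CD requires every
  member ring fully circularized (covalent catenation needs all rings
  closed). Whether the IP would also require the partner to be tagged is
  untestable here and modeled as not required.
- **Independence.** Crosslinking events are independent across interfaces
  and molecules; no cooperativity term. Band intensity is linear in
  molecule count.

For the matched tetraploid designs (4×6C vs 1×6C+3×5C, equal efficiencies
and detection fractions) the CD/CM ratio-of-ratios is 4^(k−1): 1 for the
ring model, 4 for a two-ring handcuff, 16 for k = 3 — independent of the
eᵢ, which is what makes the experiment decisive. The closed forms are
verified in the tests against exhaustive enumeration over tagged-copy
choice, ordered partner draws and every per-molecule crosslink outcome
(≤4 copies, k ≤ 3).

`simulate_entrapment_assay` multiplies the expected CM and CD fractions by
independent mean-one log-normal factors with multiplicative SD `noise_sd`
(σ² = ln(1+noise_sd²), mean-corrected so the noiseless limit is exact) and
adds fixed monomer (0.6) and concatemer (0.2) background bands; the
log-normal is a modeling choice for strictly positive densitometry noise,
matched in scale to the reported replicate scatter (SD ≈ 0.10 on a
ratio-of-ratios of ≈1 from 3 replicates).

`classify_stoichiometry` scores each candidate k by
z = |observed − predicted(k)| / SD, with the SD propagated from replicate
scatter (delta method on the two design means); ties break toward smaller k
(parsimony) and are reported. At 15% gel noise and 3 replicates the k = 1
vs k = 2 decision is correct in ≥95% of simulated experiments.

Gel lanes are quantified as percent of total lane intensity; replicate
summaries report per-band mean and sample SD (n−1), with SD reported as
null for a single lane rather than 0.

## ATPase assay

The phosphate standard curve is an ordinary least-squares line AU = a·µM + b
(RMS residual reported; fitting requires ≥2 distinct concentrations). The
hydrolysis rate is the least-squares slope of absorbance vs time over a
fixed window — default the first 10 minutes, the conventional linear phase —
divided by the curve slope, in µM phosphate/min, with the fit's r²
reported. A fixed window with diagnostics was chosen over an automatic
linear-phase detector (none is prescribed, and a detector would add a
degree of freedom the data here cannot constrain). Optional baseline
subtraction of a no-protein control series is available and off by default.
Conversion to per-complex turnover needs the complex concentration and is
left to the caller.

The simulator produces absorbance rising at true_rate × curve-slope AU/min
until an optional saturation time, then constant, sampled every 30 s for
90 min by default, with additive Gaussian noise; the noiseless round trip
through `atpase_rate` is exact, and fits on noisy series agree with the
regression standard error.

## Known limitations

- Exact matching cannot represent sequencing errors or near-duplicate loci;
  external SAM ingest exists precisely so a gapped aligner can stand in.
- The meta-profile treats the anchor as a single base although the real
  anchor element has finite width.
- The stoichiometry model does not represent nicked/relaxed topoisomers,
  2D-gel mobility, crosslinker toxicity or replication-fork passage, and
  p_CM/p_CD are free parameters, not biological estimates.
- WCE coverage profiling is available but makes no claims; only IP profiles
  are asserted in tests.
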