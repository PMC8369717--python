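# Methods

This note documents the models, conventions and numerical choices behind
`ligandkit`, and what the synthetic-data generator does and does not
emulate.

## Object model and peptide→protein mapping

An experiment binds one identification run to a protein sequence database
and optional tissue (expression + subcellular location), HLA-allele and
metadata layers. Peptide→protein assignments form a bipartite graph: edges
run only from peptides to proteins, and every edge is an exact occurrence
interval `[start, end)` (0-based, half-open) satisfying
`protein[start:end] == peptide`.

Conventions that matter:

- **Peptide identity is exact string equality.** Isoleucine and leucine are
  distinct residues even though MS cannot tell them apart; merging them
  silently would corrupt round-trips, so any I/L merging is left to the
  caller's preprocessing.
- **Coordinates are trusted when supplied.** Identification pipelines may
  report a specific localization among repeated occurrences; a row carrying
  start/end keeps exactly that interval (validated against the sequence,
  with substring search as the fallback when validation fails). Rows without
  coordinates get *all* exact occurrences, including overlapping ones.
- **No protein inference.** A shared peptide contributes to every protein it
  maps to; parsimony/razor-protein logic is out of scope.
- **Normalization on load.** Peptides are uppercased; bracketed or
  parenthesized modification annotations and the `X.PEPTIDE.Y`
  flanking-residue dialect are stripped; peptides with residues outside the
  20-letter alphabet (plus X/U/B/Z) after stripping are dropped with a
  warning rather than failing the load, because identification exports are
  messy. Duplicate `(peptide, accession, start)` triples collapse to one
  row; the load report accounts for every input row
  (input = emitted + dropped + collapsed).

## Coverage and the coverage distance

The coverage array of a protein has one integer cell per residue. Each
*distinct* peptide sequence contributes one count per occurrence interval:
a peptide repeated at two sites covers both sites (coverage is positional),
while a duplicated identification row never double-counts. Consequently the
array total always equals the summed lengths of the counted occurrence
intervals — an invariant the tests check exactly.

The per-protein dissimilarity between two experiments is the L1 distance
between coverage arrays; the experiment-level distance is the unweighted
mean of this score over a protein universe, substituting an all-zero array
where a protein was not inferred. Two choices were genuinely open:

- **Universe.** For a standalone pairwise call the universe defaults to the
  union of the two experiments' inferred proteins. For a distance *matrix*
  the universe is fixed to the union over the whole set and recorded on the
  result: with a fixed universe the distance is 1/|U| times the L1 distance
  between concatenated coverage vectors, so non-negativity, symmetry,
  identity of indiscernibles and the triangle inequality hold by
  construction. A universe accession inferred in neither of two experiments
  contributes zero regardless of its length.
- **Length weighting.** Distances are plain means by default; long proteins
  therefore carry more weight, since their arrays have more cells. A
  length-normalized variant (each protein score divided by its length before
  averaging) is available behind a flag, off by default.

The color scale used for structure rendering maps a coverage array to
[0, 1] by max-normalization (`values / max`), all zeros when the protein is
uncovered; it is monotone and invariant to positive scaling.

## Experiment comparison

Overlap matrices count exact peptide (or protein-accession) matches between
pairs of experiments on distinct-element sets; the diagonal holds each
experiment's own set size. Jaccard matrices normalize for set size. Two
empty sets get Jaccard 1.0 — they are identical, and returning 0 would
falsely signal dissimilarity — with a logged notice, since empty
comparisons usually indicate an upstream problem.

MDS is the classical (Torgerson) algorithm: double-center the squared
distances, `B = −½·J·D²·J`, eigendecompose, scale the top-k eigenvectors by
√λ. Negative eigenvalues (non-Euclidean residual) are clipped to zero and
their total magnitude reported as `clipped_mass` (exactly 0 for
Euclidean-realizable inputs). Stress is the relative residual
`√(Σ(d−d̂)²/Σd²)`. Determinism: every axis is sign-flipped so its first
nonzero loading is positive, making embeddings byte-reproducible; axes with
eigenvalues equal within 1e−12 are rotation-degenerate and follow the
deterministic order of the symmetric eigendecomposition.

## Expression and compartment integration

The presented group is the set of profiled accessions that are inferred
proteins of the experiment; the background is the *profiled-but-not-
presented* remainder (not the whole genome), because that is the contrast
the presented/non-presented question poses. Auxiliary-flagged profile
entries are excluded by default; inferred proteins absent from the profile
are excluded and counted. Either group being empty is an error — there is
nothing to compare.

The comparison uses a two-sided Mann–Whitney U test, chosen because
expression values are strongly non-normal. For combined samples n+m ≤ 12
the null distribution is enumerated exactly over all C(n+m, n) assignments
of the pooled values (valid under ties; the two-sided p is the fraction of
assignments at least as far from nm/2 as observed). Larger samples use the
normal approximation with tie and continuity corrections via
`scipy.stats.mannwhitneyu`. Identical values across both groups yield
p = 1.0 rather than an error. When a family of comparisons is run,
Benjamini–Hochberg adjusted p-values are reported alongside raw ones.
Note the asymptotic branch differs from the exact one by up to ≈0.015 in p
at the n+m = 12 switch point (at mid-range p, where it is inconsequential);
the exact branch agrees with an independent exact implementation to 1e−12
on tie-free data.

Compartment counts credit a protein once to every compartment it is
annotated with; proteins absent from the location map or annotated with an
empty list land in the reserved `unknown` bucket, which is always present
in the output. Peptide counts per compartment are distinct peptides mapping
to at least one protein of that compartment.

## Taxonomy

Organism-of-origin comes from the UniProt `OS=` header field (terminated at
the next `XX=` token, per the UniProt convention) or from a user table;
unmapped accessions resolve to the reserved token `unknown`. Filtering is
*inclusive*: a peptide survives if any of its mapped proteins belongs to a
kept organism, because silently dropping host/pathogen-shared peptides
would bias exactly the analyses the filter exists for; the ambiguity count
is logged.

## Flanking regions

Flanks are extracted per mapping interval (not per distinct peptide):
cleavage context is positional, so each repeated occurrence contributes its
own neighborhood. At protein termini flanks are padded with `-` to the
requested length; the default length is 5 residues, a conventional choice
for cleavage-context analysis, and is configurable. Position frequency
matrices are computed over the extended alphabet (20 canonical residues,
X/U/B/Z, pad) so rows always sum to 1. Information content per position is
`log₂20 − H` with the pad column excluded and the remaining frequencies
renormalized; an all-pad position has IC 0, and IC is clipped at 0 (the
entropy of the rare ambiguity codes could otherwise push it marginally
negative).

## Synthetic-data generator

The generator emulates the features of HLA class II immunopeptidomes the
analyses depend on, with a single `numpy.random.default_rng(seed)` stream
per call and byte-identical outputs under a fixed seed:

- **Proteome:** i.i.d. uniform residues, lengths uniform in (100, 400) by
  default; organism labels allocated exactly by largest remainder;
  UniProt-dialect headers with `OS=` set.
- **Identification runs:** each run samples peptides from a random half of
  the database proteins (`protein_fraction = 0.5`), reflecting that an
  immunopeptidome presents only part of the proteome and guaranteeing a
  non-presented background for the expression comparison. Half the peptides
  (`hotspot_fraction = 0.5`) come from nested ladders — a 9-residue binding
  core with independent 0–4 residue extensions on each side, the ragged-end
  families typical of class II data, ~10 peptides per hotspot — and the
  rest are placed uniformly with lengths in (9, 17). The emitted table is
  shuffled and already normalized (one row per distinct peptide–protein
  pair), and carries no coordinates, so construction exercises substring
  mapping.
- **Ground truth:** every planted interval, plus per-protein coverage
  arrays computed by an independent naive per-cell scan over the whole
  database — deliberately a second implementation, so end-to-end recovery
  is a genuine cross-check. (A planted peptide occurring by chance in a
  protein never named in any row would be counted by the scan but not by
  construction; at peptide length ≥ 9 over a 20-letter uniform alphabet the
  probability is ~10⁻⁶ per run and has never been observed in the seeded
  suite.)
- **Expression:** log-normal baseline `2^N(5, 0.5)` with presented
  accessions multiplied by `2^shift` (default shift 1, i.e. two-fold).
  These defaults give the rank-sum comparison essentially full power at
  ≥ 50 proteins per group, while shift 0 leaves the groups exchangeable.
- **Locations:** each protein unannotated with probability 0.1, otherwise
  1–3 compartments drawn from a fixed eight-compartment vocabulary.

What the generator does *not* emulate: residue composition bias, homologous
sequence families, binding-affinity or processing models, spectral-level
noise, and FDR-controlled identification errors. Tests passing on this data
therefore establish the *arithmetic* of the toolkit (mapping, coverage,
distances, counts, calibration of the statistics under clean sampling), not
robustness to search-engine artifacts or biological realism of motifs.

## Problem sizes and tolerances

The seeded test and verification runs use small instances — typically 10–25
proteins of 80–150 residues and 40–100 peptides per run, 100 runs for the
coverage recount, 10 experiments (720 ordered triples) for the metric
axioms, 2,000 null simulations at n = m = 50 and 200 power replicates for
the rank-sum calibration, and 20 seeds for end-to-end recovery and I/O
round-trips. These sizes were chosen so the full suite completes in
seconds while every check remains exact: coverage, overlap and recovery
comparisons assert equality, not approximation; MDS recovery is asserted at
1e−8; the null rejection rate is asserted within 3 binomial standard errors
of the nominal 0.05.

## Known limitations

- No protein inference; shared peptides are counted per mapped protein
  everywhere, which inflates protein-level counts relative to
  parsimony-based pipelines.
- Native search-engine formats (pepXML, mzIdentML, idXML) and spectra are
  not parsed; the delimited identification table is the canonical input.
- The experiment distance is dominated by long, highly covered proteins
  unless the length-normalized variant is enabled.
- The exact rank-sum branch enumerates up to C(12, 6) = 924 assignments;
  the cutoff is fixed, not adaptive.
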