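# Methods

This note records the models behind each stage, the defaults and why,
what the synthetic data does and does not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Abstract ranking

The ranker is a presence-based naive-Bayes discriminator. Weights are
smoothed log-odds of *document* frequency (a word counts once per
abstract), so scoring is the sum over an abstract's distinct words; this
keeps fitting and scoring on the same sufficient statistic. Smoothing is
a single pseudo-count `s` (default 1.0) applied symmetrically, which
guarantees finite weights and the limit weight → 0 as s → ∞. Tools that
rank PubMed abstracts by discriminating words do not publish a canonical
formula; this realization is the simplest one consistent with that
behaviour and is replaceable behind `fit_weights`.

P-values are empirical: null abstracts are resampled word-wise from the
pooled background tokens, with lengths drawn from the empirical
background length distribution, and
p = (1 + #{null ≥ score}) / (null_size + 1) (add-one keeps p > 0 and the
estimator conservative). Default `null_size` is 10 000; selection
defaults are top 1000 at p < 0.01. Ties in rank order break by ascending
PMID so output is input-order invariant. Training abstracts are excluded
from the ranked output, mirroring the train-vs-query split the method
assumes.

Under the bag-of-words generator the null matches the background
distribution exactly, so p-values are uniform under the null (checked by
Kolmogorov–Smirnov) and the 1% selection rate is calibrated. Real
abstracts have correlated words, so on real data the p-values should be
read as relative ranks, not frequentist error rates.

## Sentence segmentation, tagging, classification

Segmentation is rule-based: split at `[.!?]` + whitespace + capital,
protecting a short abbreviation list ("e.g.", "et al.", …). Each sentence
keeps its raw slice, so concatenation reconstructs the input exactly —
offsets stay valid for evidence highlighting.

Gene tagging is longest-match, left-to-right, token-boundary-anchored
over all dictionary synonyms. Symbols of ≤ 3 characters match
case-sensitively (otherwise "lif", "gse" and similar common strings
false-tag); longer names match case-insensitively. Interaction words
match case-insensitively; morphological variants are separate lexicon
entries (no stemming), each carrying a polarity in
{activation, repression, neutral}.

The type system: for every ordered pair of distinct-symbol gene mentions
(A before B) in one sentence, type 1 if an interaction word lies strictly
between them — when several do, the word nearest A is attributed (a
deterministic single-word rule); else type 2 if the sentence has an
interaction word elsewhere; else type 3. Gene pairs co-mentioned in an
abstract but never within one sentence yield type 4 (unordered,
alphabetical, no word). Only type 1 is pathway-grade; 2–4 are surfaced
because curators use them as leads. The strict-between reading of "in
that order" is a deliberate choice; the tests pin it against a
brute-force enumeration oracle.

## Curation rules and KGML

Human curation is replaced by a rule object: accepted types (default
{1}), a word → subtype override map for neutral-polarity mechanisms
(binds → binding/association, phosphorylates → phosphorylation), the
polarity map activation → activation / repression → inhibition, optional
allow/deny symbol lists, and a strict mode that errors on unmappable
words instead of emitting `indirect`. Direction is textual order; evidence
PMIDs accumulate across abstracts, making curation idempotent.

KGML output is built by deterministic string assembly, not a generic XML
serializer, so a given graph has exactly one byte representation: entry
ids are assigned in lexicographic symbol order from 1, relations are
sorted by (source, target, subtype), evidence lists are sorted. Graphics
coordinates use a deterministic grid (8 columns, fixed pitch) rather than
a topology-derived layering: the pathway is cyclic (self- and mutual
activations), so no layering is canonical, and the grid keeps output
stable under node insertion. Two annotations ride on standard KGML slots
so that write → read → write is the identity: age labels in the graphics
`bgcolor` (lilac = ancient, green = recent, grey = unassigned, white =
unannotated) and the fly-ortholog marker as a trailing `*` on the
display name. Evidence lives in an `evidence` attribute on `relation`,
declared optional in the packaged DTD so unextended KGML stays valid.
Unknown subtypes read back as `indirect` with a warning.

## Orthology

Similarity is Smith–Waterman local alignment with BLOSUM62, gap open 11 /
extend 1 (the standard protein-BLAST parameterization), computed with
Biopython's PairwiseAligner and cached pairwise. It is symmetric and
deterministic; an external tabular-output aligner can be hooked in via
`external_similarity_hook`.

Cluster building is BBH closure: a candidate joins when it is the best
hit of a member in its taxon and its own best hit back into the member's
taxon is already a member; iterate to a fixed point. Ties break by
ascending seq_id. The closure is a superset of the seeds and re-running
adds nothing. Ortholog-group union happens after expansion in one pass
(groups must form a partition; overlap is an input error) and recruits
carry `ko_union` provenance. Verification requires every non-seed member
to reach the score floor against at least one seed; seeds are never
removed.

Score floors are never hard-coded: `calibrate_min_score` takes a labelled
sample and returns the midpoint between the lowest within-family and the
highest unrelated score (midpoint of the means if the ranges overlap).
At the default synthetic conditions the margin is wide, so any midpoint
separates perfectly; on real data the floor should be recalibrated
against a trusted family.

## Taxonomy and gene age

The taxonomy is a validated rooted tree (unique self-parent root, no
cycles, orphan detection) loaded from NCBI-taxdump-dialect
`nodes.dmp`/`names.dmp` or an equivalent JSON. The packaged mini-fixture
pins the human lineage — cellular organisms, Eumetazoa, Coelomata,
Chordata, Euteleostomi, Eutheria, Homo sapiens — with mouse under
Eutheria, a zebrafish leaf under Euteleostomi and *D. melanogaster*
branching below Coelomata. Coelomata is retained although current NCBI
dropped it: the tree is version-pinned data, and every LCA result
carries the tree's SHA-256 checksum so results are never silently mixed
across taxonomy versions.

The LCA of a cluster is the tip-most lineage clade that is
ancestor-or-self of every member taxon (an internal lineage node in the
cluster subtends itself — degenerate-input tolerance). Ancient means
strictly rootward of the reference clade; Euteleostomi itself and
everything tipward is recent. The reference is a parameter because the
ancient/recent boundary is an analysis convention, not a biological
constant. The outgroup flag (default taxid 7227) is independent of the
label, but on any taxonomy where the outgroup branches rootward of the
reference, flag ⇒ ancient (property-tested). Histograms report every
named node on the lineage, keeping zero bins; an optional clade
whitelist reproduces coarser figure-style binning by rolling counts to
the nearest rootward whitelisted clade. Genes without a cluster (no
curated seed protein) produce no LCA result and annotate as
`unassigned`.

## Synthetic data: what it emulates, and not

The corpus generator is bag-of-sentences: filler sentences draw i.i.d.
words from a class-specific unigram table; planted interactions are
injected as template sentences that satisfy their type's syntactic
pattern exactly, and a generator self-check re-finds each planted tuple
by regex before returning. Default study conditions: 60 relevant / 240
background abstracts over a shared 40-word vocabulary with 20 topic
words enriched 5× in the relevant class; the packaged demo circuit
(Hippo arm, Cdx2 switch, pluripotency triad) planted as type-1 sentences
at multiplicity 2. This exercises ranking and extraction independently
but emulates neither grammar, anaphora, negation nor nomenclature
ambiguity — perfect recall/precision on synthetic text shows the
machinery is correct, not that real-text recall would be perfect.

The proteome generator derives one member per chosen taxon from a
uniform-random ancestor by i.i.d. per-site substitution (default rate
0.05, sequence length 90–150) plus i.i.d. decoys (default 10%). This is
adequate for BBH-recovery testing because it controls the
within-family/decoy identity gap; it does not emulate rate variation,
domains, paralogy or gene loss beyond taxon subsetting. Family sizes 2–4
taxa from {human, mouse, zebrafish, fly} give the LCA stage a spread of
origins.

## Problem sizes and determinism

Defaults are desk-scale by design: 300-abstract corpora, ≤ 10 000-sample
nulls, tens of proteins at length ~120, a 10-node taxonomy. The
end-to-end pipeline derives each stage's seed from one master seed and
iterates in sorted order throughout, so two runs with the same config
are byte-identical, including the KGML.

## Known limitations

- The ranking formula and p-value construction are stand-ins for an
  unpublished service's internals; they are calibrated and tested on
  their own terms, not validated against that service's output.
- Types 2–4 definitions follow the sentence/abstract co-occurrence
  hierarchy; other extractors draw these lines differently.
- No species disambiguation: a symbol is one node regardless of which
  organism a sentence concerns.
- BBH closure has no promiscuity control; on real proteomes with domain
  shuffling a single floor is cruder than profile-based verification.
- `bin_by_clade` requires every LCA to lie on the focal lineage;
  multi-focal analyses are out of scope.
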