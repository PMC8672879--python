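# Methods

## Charge model

Net charge is the standard Henderson–Hasselbalch group summation: each
ionizable group contributes its expected fractional charge at the given pH,
`+n/(1+10^(pH−pKa))` for basic groups (H, K, R side chains and the free
α-amino terminus) and `−n/(1+10^(pKa−pH))` for acidic groups (D, E, C, Y
side chains and the free α-carboxyl terminus). The model depends only on
residue counts; it ignores sequence context, structure and ionic strength
(no PROPKA-style environment correction and no Debye–Hückel salt
correction, even though the biology concerns salt — net charge here is a
sequence-level descriptor, not a prediction of in-situ protonation).

Tunable parameters:

* **pH** — default 7.4 (physiological operating point); any value in
  [0, 14].
* **pKa scale** — default `IPC_protein`; `IPC_peptide`, `EMBOSS`,
  `Sillero`, `Lehninger` and `Grimsley` are shipped with their published
  values. Scales differ by a few tenths of a charge unit per protein, which
  can move borderline proteins across the acidity cutoff; every output
  records the scale, and `scale_sensitivity()` reports all scales at once
  so cutoff-sensitive counts are auditable. Which pKa set a given published
  count was produced with is often unknowable; cross-scale reporting is the
  mitigation.
* **acidity cutoff** — default 3 elementary charges at pH 7.4, following
  the convention that weak acidity spans pH 3–6 and strong acidity lies
  below 3. The tie (charge exactly 3) is scored basic, because the acidic
  condition is a strict "less than". The cutoff is a parameter everywhere.
* **termini** — included by default; disable for fragments
  (`has_free_termini=False`, CLI `--no-termini`).

Ambiguity codes B, Z, X, J, U, O are tolerated, contribute zero charge and
raise one warning per sequence listing their counts — the
least-assumption policy for residues whose protonation is undefined.

Numerical notes: the isoelectric point is found by bisection on [0, 14]
(unique root since z is strictly decreasing), stopping when |z| ≤ tol
(default 1e−6) with a 200-iteration cap; sequences lacking an acidic or a
basic group have no crossing and raise an error naming the missing class.
At the interval endpoints the protonation-count limits are only approached,
not reached: at pH 14 an arginine (pKa ≈ 11.8–12.5 depending on scale)
still retains 0.7–3% of a proton, so `z(14)` sits above `−n_acidic` by an
analytically bounded truncation. Tests check the limits strictly where they
are attainable and at the analytic convergence rate otherwise. Charges are
stored at full precision, rendered to 2 decimals in tables; figure bar
labels use round-half-away-from-zero integers.

## Cluster roster and name normalization

The bacterial roster is the 21 r-proteins of the two adjacent *S10* and
*spc* operons in operon order (uS10, uL3, uL4, uL23, uL2, uS19, uL22, uS3,
uL16, uL29, uS17; uL14, uL24, uL5, uS14, uS8, uL6, uL18, uS5, uL30, uL15).
Archaea and Eukarya carry four additional r-protein genes in the equivalent
conserved cluster; their identity is roster *data*, not code — the shipped
YAML lists eS4, eL32, eL19 and eL15, following the conserved archaeal
cluster layout, and can be edited without touching code. The eukaryal
roster also carries an optional non-r-protein member (RNP1, an RNase P
protein subunit that appears alongside the cluster in eukaryal profiles);
it is excluded unless explicitly requested.

Annotations are mapped to universal names by case-insensitive
word-boundary matching against a synonym table (legacy names, gene tags,
eukaryal -e names), longest synonym first, so "L2" never fires inside
"L23". Matching is annotation-based only; no synteny verification and no
homology-search fallback for unannotated proteomes. Unmatched records are
no-matches, never guesses. Duplicate annotations resolve to the longest
sequence with a logged warning; missing members are reported and excluded
from denominators (`n_found`), never imputed.

## Halotolerance classification

Classes follow the Kushner/Kamekura/Ventosa descriptors with a fixed
precedence: (1) obligate requirement ≥ 2 M → extreme halophile; (2) grows
from low salt and tolerates > 2.5 M → extremely halotolerant; (3) grows
from low salt and tolerates > 0.5 M → halotolerant; (4) optimum inside
[0.5, 2.5] M → moderate halophile; (5) otherwise non-halophile.
Requirement-based rules outrank tolerance-based ones because obligate
requirement is the defining trait of extreme halophiles. The scheme leaves
"low salt" unquantified; 0.5 M (the lower edge of the moderate optimum) is
used. Percent w/v converts to molar with the NaCl formula weight
(M = pct·10/58.44); stated ranges are validated against ordering and the
~37% saturation ceiling. A `class_override` column exists for reproducing
externally published labels when a source classified by a different
convention. Separately from the class boundaries, the 15% w/v landmark —
the empirical point above which cluster charges collapse — is kept as a
named analysis constant.

## Trend statistic

The inverse charge–halotolerance relationship is usually stated
qualitatively; this package quantifies it as Spearman rank correlation
between a strain's salt ranking (maximum stated salt %, falling back to the
class ordinal) and (a) its count of acidic cluster members, (b) its mean
cluster charge. Significance comes from a seeded permutation null
(default 10,000 permutations, rank vectors permuted wholesale so ties are
preserved; two-sided p with the +1 correction). Spearman makes the result
invariant to monotone re-encoding of the salt axis; strain order is
irrelevant. Constant inputs yield NaN correlations flagged `degenerate`
rather than an error. No phylogenetic correction for strain relatedness is
attempted — strains are treated as exchangeable, which real panels of
related strains are not.

## Synthetic data

The generator emulates exactly the two compositional signals the analysis
rests on, and nothing else: (a) proteome-wide acidification — D/E gain at
K/R expense — increasing with halophilicity `h ∈ [0, 1]`, and (b) a
basic-residue-enriched baseline for cluster r-proteins. Residues are drawn
i.i.d. per protein from shifted composition vectors (deterministic shifts,
clipped at zero and renormalized; not Dirichlet-sampled, for
reproducibility). Defaults, chosen once as field-realistic values:

* base composition: SwissProt average amino-acid frequencies;
* `rprotein_basic_boost = 0.15` — cluster proteins at h=0 run ~26% K+R
  versus ~11% background, matching the K/R enrichment of real S10-spc
  r-proteins;
* `acid_shift = 0.06` — at h=1 the background reaches ~19% D+E and ~5% K+R,
  the compositional signature reported for extremely halophilic proteomes;
* cluster protein lengths uniform in 90–260 aa, background proteins 80–400
  aa, 200 background proteins per strain — a desk-scale stand-in for a real
  proteome, sized so a full five-class panel generates and profiles in tens
  of milliseconds.

The h → salt-range map is piecewise over five h-bands, one per class, with
tolerated_max rising monotonically from 2% (h=0) to 30% and required_min
reaching 20% at h=1; it exists to exercise the classifier, not to model
physiology. `always_basic_member` pins one roster member to the h=0
composition at every h, a constructed mirror of the empirically
never-acidic uL2. Every stream derives from one integer seed via numpy
`SeedSequence([seed, strain_index, h])`, so studies are byte-reproducible;
the seed is recorded in the metadata header and in the first FASTA record
of each strain.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: within-proteome heterogeneity beyond i.i.d.
sampling (domains, signal peptides, paralogs), codon- or phylogeny-level
structure, GC-content effects, annotation noise beyond exact synonym
strings, and the empirical fact that some real cluster members (e.g. uS14,
uL16) straddle the cutoff while others never cross it. Synthetic recovery
of the trend demonstrates that the pipeline measures what it claims under
its own assumptions, not that any particular organism behaves this way.

## Problem sizes and verification

The shipped checks use: 1,000 random sequences (length 1–500) for
charge-oracle agreement at 1e−9 against an independent 50-digit Decimal
summation; 100 sequences for bisection-vs-grid pI agreement at 1e−3 (grid
step 1e−4); 100 replicate five-class panels (4 strains per class, 10,000
permutations each) for trend recovery, requiring a negative mean-charge
correlation at p < 0.01 in ≥ 95 of 100. `scripts/acceptance.py` reruns all
of this from a single `--seed`.

## Known limitations

Charges are bulk sequence descriptors at a single pH; no structural
context. The roster's four archaeal/eukaryal extras and the eukaryal RNP1
placement are editable assumptions. Classification of strains with
conflicting published optima/requirements depends on the stated precedence;
use `class_override` to reproduce an external labelling. Real-proteome runs
depend entirely on annotation quality (paralogs are resolved by length
only, and organellar vs cytoplasmic eukaryal paralogs are not
distinguished).
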