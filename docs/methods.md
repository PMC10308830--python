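# Methods

## Problem and model

`chembib` treats a monitoring literature as a bipartite count process:
records (published articles, each with a calendar year and indexing
roles) cite substances (CASRNs). Every (record, substance) pair is one
*count*; the grand total of counts is the denominator for every share
statistic in the package. Three derived objects carry the analysis:

* **substance profiles** — per-CASRN first-report year, per-year counts
  (zero-filled over the corpus window), and total count;
* **trend tables** — year × class count matrices with percent-of-total
  series;
* **concentration curves** — per-substance totals sorted descending,
  with cumulative shares; the top-N share quantifies the Matthew effect
  (repeated measurement of already-measured substances).

The pipeline order is fixed: ingest → role filter → earliest-year
dedup → exclusion screen → classification → trends/concentration →
inventory overlap. Each stage is a pure function over explicit inputs;
every removal is tallied, so conservation (input = kept + removed)
holds at every step and is asserted in the screening report itself.

## CASRN handling

CASRNs are identifiers, not numbers: they are stored canonically with
hyphens and compared as strings. Validation checks the
`^\d{2,7}-\d{2}-\d$` pattern and the positional mod-10 check digit
(digits weighted 1, 2, 3, ... from the right, excluding the check
digit). Canonicalization strips leading zeros from the first segment
down to the two-digit minimum and is idempotent. Validation failures
are returned values, not exceptions, because readers must tally them:
a corpus export with a corrupted token should lose that token, not the
run. Malformed-pattern and checksum-mismatch failures are tallied
separately, since they indicate different upstream problems.

## Screening and classification rules

The exclusion screen (essential elements, minerals, simple inorganic
salts, polymers, natural products, mass-labeled compounds, food
constituents, ...) is *data*, not code: category CASRN files applied in
file order, with a substance attributed to its first matching category.
A whitelist (by default the well-known water-pollutant ions
perchlorate, nitrate, phosphate, sulfate, cyanide) is exempt from every
category. Making the screen declarative keeps the arithmetic testable
— the worked-example fixture reproduces the 23,458 − 3,682 = 19,776
reduction exactly — and keeps chemical judgment out of the code.

Classification is single-label with explicit precedence. Class lists
are ordered; the highest-precedence list containing a substance wins;
substances only on the broad CEC suspect-screening list become
*CEC-only*; the rest *not characterized*. Disjoint classes are a
presentation requirement of the summary exhibits, and precedence is the
one rule that makes the partition reproducible; `dedupe_lists` applies
the same rule to the lists themselves and reports every moved member.
Transformation products inherit their parent's class through an
explicit parent → TP table, never overriding a higher-precedence list.

## Percent display

Summary tables conventionally mix integer and two-significant-figure
percentages. The package fixes one rule: round-half-up; integer display
at ≥ 10%; two significant figures below; exact zero prints `0%`. All
printed percentages in the reproduced exhibits follow from this rule
applied to the printed count columns. Two known printed values (a top-10
share of 8.8% where the counts give 8.7%, and a top-200 share of 47%
where the counts give 46%) are not reproducible from their own printed
counts under any consistent rounding rule; the package reports what the
counts yield.

## Synthetic corpus generator

The generator emulates the statistical structure of a substance-indexed
citation database, which is what the analysis assumes and all that the
tests require:

* **volume**: year *y* (offset *k* from the start) gets
  `round(base · growth^k)` records; defaults `base = 100`,
  `growth = 1.08` (≈ 5-fold over two decades, the observed order of
  magnitude for environmental-measurement literature);
* **popularity**: substance of rank *r* has fixed Zipf weight ∝ `r^-s`
  (default `s = 1.0`); with attachment weight `w` (default 0.3) the
  sampling probability is `(1−w)·zipf + w·(citations so far + 1)`,
  renormalized over substances that have emerged — the preferential-
  attachment term makes the top-100 share of annual counts drift
  upward, the rich-get-richer signature;
* **emergence**: uniform emergence years over the window by default
  (`all_at_start` available); Zipf weights renormalize over currently
  emerged substances so per-year sampling is always well defined; a year
  with no emerged substance is a hard error naming the year;
* **records**: CASRNs per record are truncated-geometric (mean 4,
  matching the observed ≈ 4.4 counts per citation in this literature),
  drawn without replacement; records carry the ANST and POL roles, half
  additionally BIOL;
* **classes**: each substance draws one label from a configurable
  mixture; the default mixture is a structural stand-in — ~56% named
  classes, 15% CEC-only, 29% not characterized — mirroring the class
  composition of a screened analysis list in shape, not content.

Seeding: every stream derives from a single root seed, with per-year
substreams (`[seed, 1, year]`) so extending the window never perturbs
earlier years; identical config + seed gives a byte-identical corpus.
Ground truth (emergence years, first-cited years, classes, Zipf
weights, realized totals) is exported, and recovery must be *exact*:
first-report years, class counts, and totals are all determined by the
corpus, so any pipeline deviation is a bug, not noise.

What the generator does **not** emulate: real CASRN populations, name
or structure information, UVCB/mixture entries, role semantics beyond
set membership, journal or language structure, or any fitted match to a
real database's series (the real data are proprietary). Passing tests
therefore show the pipeline's bookkeeping and statistics are correct
under the assumed structure — not that the generator's parameters
describe any particular real corpus.

## Worked-example reconstructions

The published exhibits this package reproduces print cumulative counts,
not raw data. `chembib.worked_example` rebuilds minimal objects exactly
consistent with the printed numbers: a concentration curve over 19,776
substances whose block sums match the printed top-10/100/200/300/500
cumulative counts (within each rank block the counts are spread as
evenly as integers allow, which keeps the sequence sorted); a screening
universe at the printed sizes; and three fixture inventories whose
per-set overlaps (3,499 / 2,974 / 1,576) and union (4,253) match the
printed values, with declared sizes 67,950 / 37,100 / 16,760. The
individual Venn region counts are not printed anywhere, so the split
used (599/78/280 singles, 2,000/400/396 pairs, 500 triple) is an
arbitrary consistent choice, labeled synthetic where it is defined.

## Numerical and design choices

* Top-N ties break by canonical CASRN ascending (deterministic cuts).
* Years with zero total reports yield NaN shares, never 0: "no
  literature" and "class absent from the literature" are different
  facts.
* Dedup output order is (first_year, CASRN) — a pure function of corpus
  content, invariant to record order.
* Role vocabulary is open strings matched case-insensitively; ANST/POL/
  BIOL are conventions of one database, not an enum.
* The corpus year window is configuration (default 1900–2100 at
  ingest); rows outside it are rejected and tallied.
* Test and acceptance problem sizes (hundreds of substances for
  property tests; 5,000 substances × 30 years for end-to-end recovery)
  were chosen as the smallest scales at which the heavy-tail and
  growth structure is unambiguous.

## Known limitations

* Matching is CASRN-exact everywhere; no name- or structure-based
  matching, so UVCBs and mixtures in real inventories are out of scope.
* Classification quality is entirely inherited from the class-list
  files; the package contributes the precedence mechanics, not the
  chemistry.
* The generator's preferential attachment operates on total citations,
  not per-class dynamics; class trend shapes in synthetic corpora are
  driven by emergence and mixture only.
* No trend significance testing or smoothing is provided; the trend
  tables are raw per-year counts and shares.
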