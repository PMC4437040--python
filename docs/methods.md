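# Methods

## Record model

A sequence record is a triple (identifier, description, sequence), plus an
optional phred+33 quality string of equal length. The identifier is the
whitespace-free token after `>` (or `@`); the description is the rest of
the header line, verbatim. Descriptions are addressed as an ordered list of
fields split on a delimiter regex (default `\s+`): field 0 is the
identifier, fields 1..m are one-based, negative indices count from the last
field. This makes description-field indexing, sequence-coordinate indexing
and range syntax uniform across all tools.

Parsing is strict where silence would lose data: a `>` header with no
identifier is an error naming the line, as is a FASTQ quality/sequence
length mismatch. Field addressing is lenient where strictness would abort a
pipeline mid-stream: an out-of-range field or missing tag resolves to the
empty string for matching/sorting, and the count of such records is
reported on standard error at the end of the run. Sequence characters are
stored verbatim (case preserved); comparisons are case-sensitive unless a
tool's ignore-case flag is given. The FASTQ `+` line's content is ignored
on input and emitted bare on output. Serialization wraps sequences at 60
columns by default; parse∘serialize is the identity on
(identifier, description, sequence, quality).

Tagged values `name=value` / `name:value` occupy exactly one description
field. Lookup scans fields left to right and returns the first match —
duplicate tag names resolve to the first occurrence (a fixed convention;
the alternative, last-wins, has no pipeline advantage and first-wins keeps
lookup streaming).

## Range algebra

Three comma-separable dialects coexist: `from..to`, `from:to[:by]`, and
`from-to`, with negative indices counting from the end (−1 = last). A
missing `by` defaults to +1 ascending / −1 descending *after* endpoint
resolution, so `3..1` is a reversal rather than empty. Indices outside
1..length are dropped silently so one spec can be applied across records of
varying length; duplicates and reorderings are preserved (selection output
is the concatenation of selections). Numeric filter ranges accept
scientific notation and open ends: `100-` means ≥100, a bare `-100` means
≤100, and all finite endpoints are inclusive ("between 200 and 500
million" reads inclusively). In the two-sided `a-b` form an embedded
negative number binds to the numeral, so `-10--1` still parses.

## Selection, ordering, deduplication

`fasgrep` matches a Perl-style regex against the chosen target (identifier
by default) and the `-e` flag expands IUPAC ambiguity letters into bracket
classes (nucleotide R→[AG] … N→[ACGT]; protein B→[DN], Z→[EQ], X→[A-Z])
outside character classes and escapes only, so the expansion is idempotent
and metacharacters survive. `-e` is read as "expand ambiguities" only.
`fasfilter` takes the left-most capture group of its `-x` regex (or the
whole target) as a real number and keeps records falling in the interval
set; unparseable or missing captures drop the record. Numeric sorting
places unparseable keys after all parseable ones, preserving input order
among them, for a deterministic total order. `fasuniq` compares only
immediately successive records (sort first for global deduplication);
`uniq_count` sums to the input record count. `fastail` buffers at most
*n* records.

## Cut and paste

`fascut` selects residues (default) or description fields by index range;
cutting fields rebuilds the description with single spaces, since the
original delimiters are not recoverable after regex splitting. `faspaste`
concatenates one unit (sequences by default, descriptions with `-d`) across
parallel streams; the receiver stream (`-R N`, default 1) supplies
identifiers, descriptions and the non-pasted unit. With `-r`, any stream of
exactly one record is recycled against the rest — this single rule
reproduces both "prepend a reference to every record" usages regardless of
which stream is the receiver. Unequal stream lengths without `-r` are an
error reporting the counts. `-` may repeat; both occurrences denote one
parse of standard input.

## Transformation

`fastr` implements classic `tr` semantics over expanded character ranges
(to-set padded by repeating its last character), with deletion, squashing
of consecutive repeats, degapping (`-`), and strict-alphabet remapping:
every character outside ACGTacgt (nucleotide) or the 20 canonical
amino-acid letters in both cases (protein) becomes the replacement
character. Strict alphabets are deliberately case-preserving so
lower/upper-cased data survives a remap round trip. Following the
tool-family convention that character transforms default to identifiers,
the FROM/TO transliteration targets identifiers unless `-s`/`-d` is given;
`--degap` and `--strict` always operate on sequence data, which is the only
place gaps and ambiguity codes live. `fassub` applies one (or with `-g`,
all) regex substitution with Perl-style `$1` capture references, validated
before any record is processed. `fasconvert` infers the input format from
the leading record character; FASTA→FASTQ requires an explicit default
quality character, FASTQ→FASTA drops quality.

## Annotation

`faslen`, `fascomp`, `fascodon` and `fasxl -a` append their results as
tagged fields (`len:407`, `comp_A:120`, `cod_ATG:1`, `xl0:MKV…`), so
downstream tools can select and sort on computed properties; `--table`
variants emit TSV. Composition tags are named `comp_<symbol>` to serve as
sort keys. Codon tallies count every whole codon in the main table, with
the first codon additionally tallied as a start and a terminal stop codon
as a stop ("counted distinctly" without losing the total: the main table
always sums to ⌊L/3⌋). Genetic codes are the NCBI translation tables as
shipped with Biopython (`Bio.Data.CodonTable`); translation is gap-aware
(`---`→`-`, partially gapped codons→`X`) so aligned coding sequences
translate column-consistently, and the annotation tag is `xl<frame>`.
`fasrc` reverse-complements sequences in place under the full IUPAC
complement table (case preserved, gaps fixed points); it errors on
non-IUPAC characters, naming the offender.

## GenBank feature extraction

The flat-file parser covers the LOCUS…FEATURES…ORIGIN…// layout with
joined continuation lines and quoted multi-line qualifier values. The
location grammar is the common subset `a`, `a..b`, `complement(…)`,
`join(…)` and `<`/`>` partial markers; `order()`, `one-of()` and
cross-entry references are rejected with an explicit "unsupported
location" error rather than skipped, and coordinates are 1-based inclusive
throughout. Extraction concatenates segments in written order and
reverse-complements the joined result when the location is complemented
(for `complement(join(…))` this is the conventional reading). Emitted
records are named `<locus>_<key>_<k>` with a per-key ordinal, which keeps
identifiers unique within a run; descriptions carry the location string and
selected qualifier values. Qualifier constraints combine by conjunction:
`name=REGEX` requires a matching qualifier, `name^REGEX` forbids one.

## Alignment sites

Columns are classified by content: gap characters are `-` and `.`;
a column is invariant iff its non-gap symbols are all identical, variable
otherwise, parsimony-informative iff ≥2 distinct non-gap states each occur
≥2 times. All-gap columns are excluded from both the invariant and the
variable sets (non-all-gap selection is its own mode); `-v` inversion is
the strict set complement over all columns. Ambiguity codes count as
ordinary states — the intended workflow remaps them to gaps explicitly
before site selection. Thresholds relax modes per site: gap-free with
`-f N` tolerates ≤N gapped rows; invariant with `-f N` tolerates ≤N rows
deviating from the column's majority state. Feature projection
(`gbfalncut`) maps each ungapped reference position to its column; the
reference row is located by the GenBank accession occurring in a row
identifier, falling back to an exact degapped-sequence match, and the
reference row is checked (case-insensitively) against the ORIGIN sequence
over the feature before any column is selected.

## Taxonomy

`nodes.dmp`/`names.dmp` load into a parent-pointer tree validated for
orphans and cycles; only the "scientific name" and "synonym" name classes
are indexed, which bounds memory and covers record labelling practice.
Clade membership is ancestor-or-self along the parent path. Record labels
resolve to taxids numerically or by name, progressively dropping trailing
tokens so "species (and strain)" labels like *Rhizobium leguminosarum bv.
viciae 3841* resolve at the species; a homonymous name maps to several
taxids and membership is their disjunction. Without `--strict`,
unresolvable labels count as outside the clade (so negation keeps them);
with it they are dropped regardless of negation. The taxonomic sort key is
the tuple of canonical names along the root→taxon path, which groups every
clade contiguously.

## Population-genetic statistics

Definitions as in the README. Implementation notes:

- **Site policy.** Default is complete deletion: columns containing any
  gap or non-strict nucleotide are excluded (their count is reported on
  stderr), matching the workflow in which ambiguities are remapped and
  gapped sites removed upstream; `--as-is` keeps every column and treats
  every distinct character as a state. η is therefore counted on the same
  usable columns as every other statistic.
- **η and η_S.** η sums (distinct states − 1) per usable column, so
  η = S exactly when all segregating columns are biallelic; η_S counts
  (column, state) pairs with the state in exactly one sequence at a
  segregating column.
- **Fu & Li D\*/F\*.** Variance coefficients follow Simonsen, Churchill &
  Aquadro (1995), the corrected forms also used by the standard reference
  implementations: with a = a₁(n−1), b = a₂(n−1), a₁⁺ = a + 1/n,
  cₙ = 2(na − 2(n−1)) / ((n−1)(n−2)),
  dₙ = cₙ + (n−2)/(n−1)² + (2/(n−1))·(3/2 − (2a₁⁺−3)/(n−2) − 1/n),
  v_D\* = [(n/(n−1))²b + a²dₙ − 2na(a+1)/(n−1)²] / (a²+b),
  u_D\* = (n/(n−1))(a − n/(n−1)) − v_D\*, and the analogous u_F\*/v_F\*.
  D\* = ((n/(n−1))η − a·η_S)/√(u_D\*η + v_D\*η²);
  F\* = (Π − ((n−1)/n)η_S)/√(u_F\*η + v_F\*η²). Both need n ≥ 3.
- **Degenerate denominators.** At n = 3 Tajima's variance constants
  vanish identically (c₁ = c₂ = 0), and the D\*/F\* variances can do the
  same. A zero numerator is still an exact null result, so statistics with
  numerator 0 report 0; a non-zero numerator over a non-positive variance
  reports NA. S = 0 (or η = 0) is always NA, never 0, and NA is rendered
  as the string `NA` in TSV so downstream parsers cannot mistake undefined
  for zero.
- **E(K).** Ewens' expectation is evaluated at θ = θ_W per locus from the
  same alignment (the estimator available without further modelling
  choices).
- **Windows.** Windows start at columns 1, 1+step, …; only full-width
  windows are emitted, and each window's statistics are computed on its
  column slice under the same site policy, so a window of the full
  alignment width reproduces the whole-alignment values exactly.
- **Pairwise mode** emits the n×n matrix of pairwise difference counts
  over usable columns.

## Synthetic data

All fixtures are generated, deterministic under a seed, with their
planted quantities recoverable exactly by counting:

- **Planted alignments** place chosen state multisets at chosen columns on
  a monomorphic background; S, η, η_S follow by construction. The worked
  3×4 alignment (ACGT/ACGA/TCGA) has S = η = η_S = 2, k = 3, Π = θ_W = 4/3
  and D = D\* = F\* = 0.
- **The coalescent sampler** implements the standard neutral coalescent
  with infinite-sites mutation: exponential waiting times with rate
  C(k,2), Poisson mutations with mean θ/2 per unit branch length dropped
  uniformly on branches, each mutation a biallelic column (carriers T,
  others A). Under this model E[S] = θ·a₁ and E[Π] = θ, which the
  calibration tests check at n = 10, θ = 5 over 2000 replicates — sizes
  chosen to put Monte-Carlo error comfortably inside the 10% band while
  keeping the run under a couple of minutes on one core. The sampler has
  no recombination, no finite-sites homoplasy and no rate heterogeneity,
  so passing calibration shows the estimators are correctly normalised
  under the neutral model, not that they are robust to real-data
  violations of it.
- **The PopSet-style alignment** is a synthetic stand-in emulating a
  population set of one annotated reference plus partially sequenced
  allelic variants: gi-style identifiers, shared gap columns, scattered
  ambiguity calls, ~3% polymorphic sites. Exactly six of its 24
  identifiers match the filter pattern `(AF194|349[06])` by construction,
  giving identifier-based filtering a known ground truth. It is not NCBI
  data; conclusions about real PopSet alignments are limited accordingly.
- **GenBank and taxdump fixtures** render the respective flat-file
  dialects from explicit feature/tree specifications and are checked by
  round trip; the GenBank fixture is also parsed with Biopython in the
  tests as an independent reader.

Statistics are additionally cross-checked against tskit on msprime
simulations (Π, S and Tajima's D agree to floating-point precision on
binary-mutation tree sequences).

## Known limitations

- Alignment interchange is FASTA only; no clustal/phylip/nexus.
- The GenBank location grammar excludes `order()`, `bond()`, `one-of()`
  and cross-entry references by design.
- Taxonomy loading ignores `merged.dmp`/`delnodes.dmp`; renamed or deleted
  taxids must be resolved upstream.
- `fassort` and `fastail` buffer in memory (no spill-to-disk merge sort);
  all other tools stream.
- Fu & Li's outgroup-based (unstarred) D and F, and Fu's F_S, are not
  implemented.
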