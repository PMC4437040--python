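# fastools

Composable Unix-pipeline tools for biological sequence records: selection,
transformation, annotation, GenBank feature extraction, alignment-site
algebra, NCBI-taxonomy filtering, and molecular population-genetic
statistics.

`fastools` treats a multi-FASTA file or stream as a database. Each record
has an identifier (field 0), an ordered list of regex-delimited description
fields (1..m, one-based; negative indices count from the end) and a
sequence; Sanger/Illumina 1.8+ FASTQ is supported as well. Every tool reads
from files or standard input, writes records (or TSV tables) to standard
output and diagnostics to standard error, so arbitrary workflows compose
with ordinary Unix pipes — `grep`, `cut`, `tr`, `sort`, `uniq`, `head`,
`paste` and `wc` all have record-aware analogues here (`fasgrep`, `fascut`,
`fastr`, `fassort`, `fasuniq`, `fashead`, `faspaste`, `faswc`), joined by
tools for numeric and taxonomic filtering, format conversion, computed
annotations (lengths, compositions, codon usage, translations, reverse
complements), GenBank feature extraction (`gbfcut`, `gbfalncut`),
alignment-column selection (`alncut`) and population genetics (`alnpi`).

Computed annotations travel *inside* the stream as tagged description
fields (`name:value`), so a pipeline can translate sequences, select on a
protein motif, and then strip the annotation again without any side files.

## The statistics core

For an alignment of *n* sequences over *L* usable sites, `alnpi` reports:

- *S*, *s* — number and fraction of segregating sites; η — total mutations,
  Σ per column (distinct states − 1); η_S — singleton mutations; *k* —
  distinct sequences;
- Π = (1/C(n,2)) Σ_{i<j} d_ij and π = Π/L — mean pairwise differences per
  locus and per site (Nei & Li);
- θ_W = S/a₁ with a₁ = Σ_{i=1}^{n−1} 1/i — Watterson's estimator;
- E(K) = Σ_{i=0}^{n−1} θ/(θ+i) — Ewens' expected allele count;
- Tajima's D = (Π − S/a₁)/√(e₁S + e₂S(S−1));
- Fu & Li's D\* and F\* — outgroup-free neutrality tests contrasting η_S
  with η (D\*) or with Π (F\*), using the Simonsen–Churchill–Aquadro
  corrected variance coefficients.

Undefined statistics are printed as `NA`, never 0. Sliding-window mode
(`--window WIDTH:STEP:CODES`) profiles any of D/π/θ_W/S along an alignment.

## Worked example

Start from the bundled synthetic PopSet-style alignment (24 gapped,
partially ambiguous allelic variants), drop six reference/deactivated
records by identifier regex, neutralise remaining ambiguities, keep
gap-free columns, and profile Tajima's D in overlapping windows:

```sh
fast-fixtures popset > popset.fas
fasgrep -v "(AF194|349[06])" popset.fas | faswc
# 18      6480    -
fasgrep -v "(AF194|349[06])" popset.fas | fastr --strict -N - \
  | alncut -g | alnpi --window 100:25:d
# alignment  window_start  window_end  tajima_D
# stdin      1             100         2.38501
# stdin      26            125         2.20941
# ...
# stdin      201           300         0.439453
```

`faswc` confirms the filter removed exactly 6 of the 24 records (18
remain); each table row is Tajima's D over one 100-column window advanced
in steps of 25 across the 316 gap-free columns. Whole-alignment statistics
come from plain `alnpi`:

```sh
fast-fixtures worked | alnpi
# alignment  n  k  L  S  s    Pi       pi        theta_W  ...  D  Dstar  Fstar  eta  eta_S
# stdin      3  3  4  2  0.5  1.33333  0.333333  1.33333  ...  0  0      0      2    2
```

Annotation tools compose the same way — for instance, selecting coding
sequences whose translation carries an N-glycosylation motif and restoring
the original records afterwards:

```sh
fasxl -a cds.fas | fasgrep -t xl0 "N[^P][ST][^P]" | fascut -f 1..-2
```

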