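# Methods

## The problem

Some organisms cannot be grown to the cell densities that direct shotgun
sequencing needs. A common workaround is whole-genome amplification (WGA)
of the little DNA a pure culture yields, but multiple-displacement WGA
produces reads that are frequently *chimeric* — junctions of two
non-adjacent genomic loci — and its coverage is strongly uneven, so WGA
reads alone assemble poorly. When the organism grows well in a defined
co-culture with a single partner, an alternative is to shotgun-sequence the
mixed co-culture DNA (which assembles cleanly but contains two genomes) and
to use the WGA reads only as *bait*: they need not assemble, only vote on
which co-culture contigs belong to the target organism.

`diffpick` implements this differential reads picking procedure end to end,
with a truth-labelled simulator of the experimental design and the
downstream genome characterisation used to describe the recovered genome
(genome statistics, ANIb, CRISPR arrays).

## The picking procedure

Inputs: a WGA bait library from the pure target culture; co-culture
direct-shotgun reads on two platforms — platform A, long single-end reads
(~400 bp), and platform B, 251 bp paired-end reads.

1. Assemble the platform-A reads (all of them — both organisms).
2. Map the bait reads to the resulting contigs.
3. Recover the platform-A reads placed on bait-supported contigs
   (default: ≥ 1 assigned bait read). These are attributed to the target.
4. Quality-trim the platform-B pairs, subsample them to ~100× the expected
   target genome size, and co-assemble them with the step-3 reads.
5. Pick the platform-B reads placed on co-assembly contigs that also carry
   at least one step-3 read. The published description ("reads co-assembled
   with" the long reads) does not define the membership test; contig
   co-membership is the most direct reading and is what we implement.
6. Re-assemble all picked reads into the final assembly.

The original procedure finished with manual closure of the assembly. We do
not automate joining — that would overclaim — and instead emit a
scaffolding *report*: contig pairs ranked by the number of mate pairs whose
ends place on different contigs, with their orientation class.

Trimming precedes subsampling (step 4); the published order is unstated and
this is the conservative choice (bases are counted after trimming, so the
coverage target refers to usable bases).

### Assembly and mapping internals

The original work used a proprietary assembler/mapper. Since the goal is
read *binning*, not assembly polish, `diffpick` ships a minimal de Bruijn
assembler: canonical k-mers (k = 31) with count ≥ `min_kmer_count`
(default 2), tip clipping (dead-end unitigs shorter than 2k, up to 3
rounds), and maximal non-branching paths of length ≥ 2k as contigs. There
is no bubble popping or error correction beyond the count filter; at the
coverages used, recurrent sequencing errors therefore fragment contigs
somewhat. This is a documented limitation — it costs a few percent of
assembly contiguity but does not disturb binning.

Reads are placed on contigs by canonical k-mer voting: a read is assigned
to the contig collecting the largest fraction of its k-mers on a consistent
strand, if that fraction reaches a threshold. Two thresholds matter:

| parameter        | default | why |
|------------------|---------|-----|
| `assembly_k`     | 31      | standard short-read de Bruijn order; odd so no k-mer is its own reverse complement |
| `bait_k`         | 21      | more sensitive mapping of baits onto draft contigs |
| `min_frac_ds`    | 0.5     | direct-shotgun reads should match near-fully; 0.5 tolerates a few sequencing errors |
| `min_frac_bait`  | 0.3     | a chimeric bait legitimately matches over only part of its length |
| `min_bait_reads` | 1       | any bait-mapped contig counts as target-supported |
| `target_cov`     | 100     | subsampling target for the platform-B stream |

Ties (two contigs with equal top votes) leave the read unassigned — a
conservative rule that protects picking precision at a small cost in
recall. Mates are assigned independently and reconciled at pick time: if
either mate of a pair qualifies, the pair is picked whole.

## The simulator

`simdata` generates the full experimental design with per-read truth
labels: two i.i.d. random circular genomes (default 47% G+C), platform-A
reads with Normal(400, 80) lengths, platform-B proper innie pairs with
Normal(500, 50) inserts, i.i.d. substitution errors at 0.2% per base
(representative of modern short-read substitution rates; indels are not
modelled), and Phred qualities decaying mildly along the read. The WGA
bait library adds the two artifacts that motivate the method: chimeric
reads (probability `wga_chimera_rate`, default 0.1 — the real chimera rate
was never measured, so this is a free parameter — junction point uniform
along the read, the two segments drawn independently with uniform locus and
strand) and window-level amplification bias (5 kb windows weighted
lognormal(0, σ = 1)).

The reference scenario (`standard_scenario`) is two 100 kb genomes at
equal abundance with no shared sequence, platform A at 20× and platform B
at 100× per genome, baits at 10×. Genome sizes are scaled down ~15-fold
from a real bacterial chromosome so that a five-seed recovery suite runs on
a laptop; k-mer uniqueness at 100 kb already behaves like the full-size
problem for binning purposes. A `shared_frac` knob implants target sequence
into the contaminant to reproduce the method's known failure mode: baits
cannot distinguish genuinely shared sequence, so precision degrades as
sharing rises.

What the simulator does *not* model: indel and homopolymer errors, PCR
duplicates, more than two organisms, adapter read-through, GC-dependent
coverage bias of the shotgun libraries. Passing tests therefore demonstrate
the method's logic under its intended conditions, not robustness to every
real-data artifact.

Recall is scored against the candidate universe the recovery steps see:
all platform-A reads, and the platform-B reads surviving trimming and the
prescribed 100× subsampling. Subsampling is a deliberate throughput step of
the method, not a picking error, so reads it removes are not counted as
misses. Precision, completeness (target 31-mers present in the final
contigs) and contamination (contaminant-only 31-mers in the final contigs)
are computed over the full final assembly.

## Quality trimming

A sliding-window trimmer reproducing the classic windowed algorithm:
window = 10% of the read length, kept region from the first window with
mean quality ≥ Q20 to the first later window below it, minimum length
20 bp. Both mates surviving → pair kept; one → orphan single (the singles
stream participates in step 4); none → discarded. Long platform-A reads are
not quality-trimmed, matching the original protocol, which trimmed only
the short-read stream.

## ANIb

The query genome is cut into non-overlapping 1020 bp fragments (a final
fragment shorter than 100 bp is dropped); each fragment is aligned to the
reference on both strands; hits with identity ≥ 30% covering ≥ 70% of the
fragment are retained; the ANI is the mean identity of retained best hits.
These cutoffs are the established ANIb defaults.

The alignment engine is a pluggable contract
(`engine(fragment, reference) -> (identity_pct, coverage_pct)`). The
built-in engine uses edlib semi-global alignment (the fragment aligned
end-to-end against its best-matching stretch of the reference), with
identity computed as matches over alignment columns from the extended
CIGAR. Because this engine always consumes the whole fragment, the 70%
coverage filter never fires with it and filtering is effectively driven by
the identity cutoff; a local (Smith–Waterman/BLAST-style) engine can be
plugged in where partial-fragment hits matter. Consequences: self-ANI is
exactly 100; substitution-only divergence d maps to ANI ≈ 100(1 − d); and
ANIb is not exactly symmetric (tested to within one percentage point).

## CRISPR array detection

An array is ≥ 3 copies of a direct repeat of 23–55 bp separated by spacers
of 0.6–2.5× the repeat length, with spacers mutually dissimilar (< 60%
pairwise identity — this is what separates a CRISPR array from a tandem
repeat). Copies may diverge from the consensus by ≤ 20% of positions;
terminal copies by ≤ 33%. The reference online tool never published exact
pseudocode, so these thresholds (all exposed in `CrisprParams`) implement
its published description.

Detection seeds on exact 23-mers occurring ≥ 3 times with inter-occurrence
gaps inside the feasible period range, extends the seed into the full
repeat column-by-column (a column is accepted while ≥ 80% of copies agree
and no spacer would fall below its lower bound), then searches both flanks
for degenerate terminal copies with edlib. Overlapping candidates are
resolved by repeat count, then span. Coordinates are 1-based inclusive;
the span runs from the first repeat start to the last repeat end, reported
on the forward strand as written (no reverse-strand canonicalisation). The
consensus is the per-column majority (ties → IUPAC codes; for unequal copy
lengths, trailing columns need ≥ 50% occupancy), accompanied by a
per-column conservation vector.

## Genome statistics

From an annotated record (GenBank subset: CDS/tRNA/rRNA/tmRNA, `join`/
`complement` locations, `/pseudo` flags): genome size, G+C count and
percentage (ambiguity codes stay in the denominator), coding bp as the
strand-agnostic merged union of CDS segments (the only convention bounded
by genome size, hence compatible with "% of total ≤ 100" semantics; the
summed alternative is available as `coding_bp_summed`), CDS/RNA/pseudogene
counts and total genes = CDS + RNA. Percentages are rounded half-up to two
decimals, the convention of published genome tables. Pseudogene counting is
best-effort: annotation pipelines encode pseudogenes inconsistently.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed and configuration reproduce byte-identical reads and assemblies.
* Contig ordering is fixed (length descending, then
  min(sequence, reverse complement) lexicographically), so assemblies of
  the same read multiset compare equal.
* Empty selections at any pipeline step abort with a diagnostic naming the
  step rather than propagating empty sets.
* `evaluate` defines precision as `None` (not 0) when nothing was picked.
* An ANIb run with no retained fragments returns a null ANI rather than 0.
* Reads shorter than k are excluded from assembly and placement; an input
  whose every read is shorter than k is an error.

## Known limitations

* No bubble popping: recurrent substitution errors at high coverage
  fragment contigs (completeness plateaus around 95–96% in the reference
  scenario); harmless for binning, wrong tool for polishing.
* Chimeric baits whose two segments both come from the target are handled;
  chimeras across organisms cannot occur in the design (WGA runs on the
  pure culture) and are not simulated.
* The k-mer voting mapper has no notion of paired placement consistency;
  pairing is enforced only at pick time.
* ANIb values on real genome pairs depend mildly on the alignment engine;
  agreement with published values computed by BLAST-based tools is expected
  to ±0.3 percentage points, not to the last digit.
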