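# Methods

## The model

An sxRNA interaction is a *trans* three-way junction: an mRNA stem-loop
(helix 1) whose two flanking segments are base-paired by one small ncRNA
(helices 2 and 3), the three helices meeting around a junction of unpaired
bases. The detector works entirely on secondary structure: given the joint
(mRNA segment, ncRNA) structure as a pair table, it asks

1. is the motif's own stem-loop present (all stem pairs formed
   intramolecularly, and — by default — no loop base paired to the ncRNA);
2. does the ncRNA pair to the mRNA on *both* sides of the stem within a
   configurable reach;
3. are the junction sizes and helix qualities within thresholds.

Anchor positions are defined extremally: on each side of the stem, the
intermolecularly paired mRNA base nearest the stem (blue) and farthest from
it (orange), plus the ncRNA partners of the blue bases (green). Junction
sizes follow from the anchors: `mJ5 = purple5 − blue5 − 1`,
`mJ3 = blue3 − purple3 − 1`, `nJ = |green5 − green3| − 1`, where purple5/3
are the bottom stem bases. Trans-helix quality is measured as the
intermolecular pair count within each blue–orange extent and the paired
fraction of that extent, so interior bulges are tolerated but penalized.
Antiparallel geometry requires the 5′ flank to engage the ncRNA's 3′ side;
candidates with interleaved green anchors are rejected (`arm-order`), though
with a single nested bracket family this cannot actually arise.

Classification: *inducer* requires checks 1–3 to pass; *repressor* requires
positive ablation evidence — at least `min_ablation_pairs` intermolecular
pairs on the motif's stem∪loop — together with a broken stem, so a motif
that merely fails to fold for cis reasons is not miscalled; anything else is
*none*, with each failed requirement recorded verbatim in the report.

## Thresholds

All thresholds are configuration (`Thresholds`), with defaults chosen from
the sizes tolerated by natural cis three-way junctions and from ordinary
hybridization quality:

| parameter | default | meaning |
|---|---|---|
| `max_mJ5`, `max_mJ3`, `max_nJ` | 8 | max unpaired bases per junction segment |
| `min_helix_pairs` | 4 | min intermolecular pairs per trans helix |
| `min_flank_paired_frac` | 0.6 | min paired density within each helix extent |
| `min_ncrna_paired_frac` | 0.5 | min fraction of ncRNA bases paired |
| `min_stem_frac` | 1.0 | fraction of motif stem pairs required |
| `require_loop_unpaired_trans` | true | loop may not pair the ncRNA |
| `min_ablation_pairs` | 3 | evidence needed for a repressor call |
| `max_reach` | window flank (25) | how far from the stem a splint may sit |

Relaxing any single bound can only grow the inducer set (tested as a
monotonicity invariant).

## Folding backends

The scientific content of this package is the junction parsing, which is
agnostic to how the joint structure was produced. Two backends satisfy the
same contract:

* **reference** — a Nussinov-style maximizer of total pair weight
  (G·C = 3, A·U = 2, G·U = 1) on the concatenated sequence, with a ≥ 3-base
  hairpin loop for intramolecular pairs and no distance constraint across
  the strand break. It is dependency-free and bit-reproducible, which the
  test suite and synthetic benchmarks rely on. Weight ties are resolved
  lexicographically toward structures with more stacked pairs — integer
  pair weights are massively degenerate, and among equal-weight structures
  the stacked one is the thermodynamically sensible representative;
  residual ties prefer leaving the 5′-most position unpaired, then the
  smallest partner index. The structure returned for a given input is
  therefore unique and stable.
* **external** — ViennaRNA's `RNAcofold` (minimum free energy, full
  nearest-neighbor model), for production scans. Unavailability is a hard
  error, never a silent fallback. Scores are backend-scoped (pair weight
  vs kcal/mol) and are reported but never compared across backends.

Whole-message mode is guarded by a transcript-length cap (default 5000 nt)
because the reference fold is O(n³); windowed mode (±25 bases) is the
intended default and matches the junction's local geometry.

## Synthetic data generator

`fixtures` produces three kinds of records, all seeded and deterministic:

* **Motif transcripts** — one descriptor instance (random stem, random
  loop, fixed AA bulge) between random flanks. Flanks are grown base by
  base under rejection rules that make the later-designed splint structure
  *dominant*, not merely tied, under the reference scorer: no ≥ 4-base
  complementary run between flanks, or between either flank and the motif,
  in either orientation (a splint arm is a flank's reverse complement, so
  both orientations matter); no equal-weight "slippage" alternatives at
  helix ends (loop bases that could steal the bottom stem pair, bulge bases
  that could absorb an arm pair or merge the stem into the 3′ flank); and a
  G·C closing pair at the stem base, as in the natural HSL, so the junction
  is strongly anchored. Exactly one descriptor match must remain.
* **Designed splints** — the ncRNA is the reverse complement of the flank
  segment just 3′ of the stem, then `gap` junction bases, then the reverse
  complement of the segment just 5′ of the bulge. Junction bases are chosen
  deterministically (preferring A/U) so they cannot pair the mRNA-side
  junction or the bottom stem pairs. By construction the designed structure
  has `mJ5 = |bulge|`, `mJ3 = mJ3_gap` (default 0, flush; a symmetric
  non-flush option), `nJ = gap`, `h5_pairs = arm5_len`,
  `h3_pairs = arm3_len` — the ground truth for parameter-recovery tests.
  A nonzero `mismatch_rate` scrambles arm bases and voids the truth.
* **Negative controls** — *ablators* (reverse complement of loop+3′ stem,
  optionally extending into the 5′ stem): ncRNAs that hybridize onto the
  conserved motif itself, the repressor geometry; and *decoys*:
  dinucleotide-shuffled splints (Altschul–Erickson Eulerian-walk shuffle,
  redrawn up to 20× to minimize residual complementary runs against the
  source transcript).

What the generator does **not** emulate: miRNA biology (seed pairing,
expression, conservation), long transcripts with competing long-range
structure, proteins, or kinetics. Recovery and detection rates on these
fixtures certify the detector's bookkeeping and the pipeline's coordinate
handling — not the prevalence or validity of sxRNA interactions in real
transcriptomes.

## Measured behavior and known limitations

Numbers below are what `scripts/acceptance.py` recomputes (n = 200 designs,
arms 4–10, gaps 0–6; n = 100 decoys/ablators; seeds vary):

* Junction annotation recovers designed parameters exactly on designed
  structures (100 %), and agrees with a brute-force extremal-pair oracle on
  random pair tables (100 %).
* The reference fold score equals the exhaustive optimum on all random
  pairs with combined length ≤ 22 (100 %).
* The end-to-end scan classifies ~99 % of mismatch-free designs as
  inducers, and the adenosine bulge is unpaired in every detected inducer.
* **Specificity against shuffled decoys is poor under the reference
  backend (~30–45 % of decoys still classify as inducer; ~20 % under
  RNAcofold).** A dinucleotide shuffle of a 12–24 nt splint preserves
  composition and many short complementary runs, and a pair-count maximizer
  with no loop or lone-pair penalties will realize any of them, so
  scattered 2–3-pair helices routinely satisfy the default thresholds while
  the (deliberately strong) fixture stem stays intact. This is an intrinsic
  property of scoring hybridization by pair counting; real screens should
  use the thermodynamic backend and treat the decoy rate as the method's
  empirical false-positive floor, not as noise to be filtered.
* Ablators classify as repressors in ~75–90 % of cases under the reference
  backend; the remainder fold into mixed structures that leave partial stem
  pairing.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally; GFF3 output
  converts to 1-based inclusive at the boundary.
* N is accepted in transcripts and never pairs; records are normalized
  (T→U, uppercase) on input, and normalization is idempotent.
* Motif descriptors support IUPAC sequence elements and one tagged stem
  (wobble allowed by default, per-stem mismatch budget); pseudoknotted
  descriptors and insertion/deletion wildcards are out of scope. Wobble
  pairs used by a match are counted so downstream strict-WC filtering is
  possible.
* `parse_dotbracket` accepts the single nested bracket family only;
  pseudoknot families are rejected at parse time with a position.
* Report rows are emitted for every scanned combination (`--hits-only` to
  filter), sorted by (transcript, motif start, ncRNA, mode); reruns are
  byte-identical under the reference backend.
* miRNA records are scanned as given: no star/mature expansion, no
  deduplication of overlapping candidates.
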