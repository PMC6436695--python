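# Methods

## Structure model and composition rules

An LCO is modeled as: backbone length *n* ≥ 2 (GlcNAc residues), a
mandatory fatty acyl chain (c carbons, u double bonds) on the non-reducing
terminal nitrogen, and at most one each of NMe, S, Cb, Hex, plus an
optional de-N-acetylated residue. The elemental formula is assembled as

```
base(n)   = n·C8H15NO6 − (n−1)·H2O          (β-1,4 chito-oligosaccharide)
acylation = − C2H3O + CcH(2c−1−2u)O          (acetyl → fatty acyl exchange)
NMe +CH2   S +SO3   Cb +CHNO   Hex +C6H10O5   dNAc −C2H2O
```

The rules commute, and positional dNAc isomers share a formula by
construction. Sanity anchors: V (C18:1) → C₅₆H₉₇N₅O₂₆; with NMe and S the
neutral mass is 1349.615 Da, matching published masses for the sulfated
pentameric Nod factors of this strain.

**Residue numbering.** The printed tables report "deacetylated at
glucosamine residue number 3/4" without stating the counting direction.
This package counts from the non-reducing (acylated) terminus, residue 1
being the acylated residue itself — which therefore can never be the
deacetylated one. The choice has no mass consequence (isomers are
formula-identical); it only affects which B/Y fragment carries the −C₂H₂O
delta.

**Canonical serialization.** Substituents print in the order NMe, Cb, S;
`-Hex` attaches to the Roman numeral; `dNAc` is a trailing token with the
position carried out-of-band (a column in the machine-readable inventory),
mirroring how the printed table encodes it in footnotes. Parse∘format is
the identity on this dialect.

## Mass calculus

Isotope masses and abundances come from the NIST table bundled with
pyteomics; monoisotopic mass uses the lightest natural isotope, average
mass the abundance-weighted mean (this reproduces standard atomic weights
to printed precision, e.g. C₆H₁₄O₆ → 182.172). The proton mass is
1.007276466 Da. Default adducts are [M+H]⁺ and [M+Na]⁺ at charge 1
(positive-mode acquisition; the sodium adduct delta is the Na⁺ cation mass
22.989218 Da).

**Isotope envelopes** are nominal-mass aggregated: each element contributes
a distribution over neutron-count offsets, raised to its atom count by
convolution squaring and convolved across elements, truncated to the first
4 peaks and renormalized. Fine structure within one nominal mass is
deliberately merged — at orbitrap resolving powers the envelope score
operates on unit-spaced peaks. The implementation is exact within floating
point; the test suite checks it against exhaustive isotopologue enumeration
for all formulas with ≤ 8 atoms at 1e-9 absolute tolerance.

**Envelope score** is the cosine similarity (×100) of the two envelopes
aligned by nominal offset, with missing peaks as zeros: 100 iff
proportional, 0 on disjoint support, symmetric and scale-invariant. The
acceptance gate defaults to ≥ 80%. Cosine was chosen because the vendor
score it stands in for is unpublished; any monotone envelope-agreement
measure gated at a comparable level behaves equivalently at these
signal-to-distortion ratios.

**Fragments.** For each of the n−1 glycosidic bonds the engine predicts a
B ion (non-reducing portion as oxocarbenium: neutral fragment − H₂O +
charge carrier) and a Y ion (reducing portion + charge carrier). The acyl
chain, NMe and Cb travel with the non-reducing fragment, S and Hex with
the reducing fragment (Cb and Hex placements are assumptions — the
attachment residues are not fixed by the inventory); dNAc follows its
residue. Complementarity m(Bᵢ) + m(Y_{n−i}) = M + 2·δ holds identically
and is asserted over the whole inventory. Only singly charged fragments
are modeled.

## Candidate enumeration

The default configuration enumerates backbones n ∈ {3,4,5}, acyl chains
{14:0, 16:0, 16:1, 18:0, 18:1, 20:0, 20:1}, every subset of
{NMe, S, Cb, Hex} with S and Cb mutually exclusive, and dNAc at internal
residues (2–4) of pentamers: 504 candidates in 336 formula groups. This
covers all 36 inventory structures. It does not attempt to reproduce any
particular published database size — the enumeration rules behind the
1114-compound screening library referenced in prior work are not specified
there, so the count is explicitly not a contract; the configuration is
user-editable.

## Annotation

Precursors are matched per adduct through a sorted-m/z binary-search
window (proved equivalent to the all-pairs scan in tests), gated on
|ppm| ≤ 5, envelope score ≥ 80, and — only when an MS2 scan exists — at
least one B/Y fragment matched within 10 ppm. Accepted hits deduplicate to
one per formula group per run (minimal |ppm|, then higher score, then
lexicographic name); multiple adducts of one compound count once.
Per-condition presence is the union over the condition's runs.

Because exact mass cannot separate formula-identical isomers, the presence
matrix runs in two modes, recorded in output metadata: *provenance-aware*
(generator ground truth restricts a group hit to the members actually
planted — used for synthetic benchmarks) and *mass-only* (a group hit
marks every inventory member of the group — the honest behavior on real
data).

## Synthetic data generator

The generator emulates positive-mode top-N data-dependent acquisition of
an LCO extract as labeled peak lists:

- one precursor per planted structure, adduct drawn [M+H]⁺ : [M+Na]⁺ at
  0.8 : 0.2, m/z multiplied by (1 + U(−j, +j)·10⁻⁶) with j = 2 ppm by
  default — inside the 5 ppm gate, as instrument accuracy was in the
  study;
- the theoretical 4-peak envelope at 1.00335 Da spacing, each abundance
  multiplied by a log-normal factor (σ = 0.05 default);
- MS2 = the structure's B/Y ladder with the same jitter, granted only to
  precursors winning a top-5 slot among the up-to-8 co-eluting precursors
  of their acquisition cycle (losers keep MS1-only records, which the
  fragment policy correctly does not penalize);
- 20 decoy compounds by default: ±CH₂/±O formula perturbations of real
  candidates, accepted only if ≥ 20 ppm from every candidate adduct mass
  (near-misses that can never legitimately match at 5 ppm); bounded
  retries, error if the space is too dense;
- Poisson(10) uniform noise precursors with single-peak envelopes.

All randomness flows from one `numpy` generator seeded by the run seed;
identical seeds give identical runs. The four-condition driver derives
per-condition seeds deterministically from the master seed and plants
exactly the structures flagged detected in that condition's inventory
column (36 / 6 / 4 / 4).

What the generator does *not* emulate: chromatographic peak shapes,
retention times, realistic intensity response, isotope fine structure,
multiply charged species, in-source fragmentation. Passing the synthetic
benchmarks therefore demonstrates the correctness of the matching logic
and its gates under controlled error models — not identification
performance on real instrument data.

## DEG stage

The stage consumes per-gene statistics (it never refits a DE model):
signed fold-changes (r ≥ 1 → r, r < 1 → −1/r) filtered inclusively at
|FC| ≥ 2.5 with BH-adjusted p ≤ 0.05. The inclusive cut is a documented
choice (the verbal definition does not distinguish > from ≥). Records with
missing adjusted p are excluded and counted. Table readers auto-detect the
fold-change dialect — nonzero values inside (−1, 1) are impossible under
the signed convention and flag a log2 table — and the BH adjustment is
delegated to statsmodels, cross-checked in tests against a direct step-up
evaluation.

The synthetic DE table defaults to the 6289-gene genome split across the
chromosome (3672 CDS) and plasmids pA (212), pB (500), pC (1905), planting
743 DEG of which 461 up-regulated: 333/135 (up/down) on the chromosome,
66/1 on pB, 19/17 on pC. Those three replicons account for 571 of the 743;
the remaining 172 are placed on pA with the residual direction split
(43/129) so the totals close — the source counts leave this remainder
unallocated, and pA is the only replicon without a printed breakdown.
Planted genes draw |FC| = 2.5 + Exp(2) and raw p ≤ 10⁻⁷; nulls draw ratios
log-normal(0, 0.1) and uniform p. Null genes can survive the FDR gate but
never the fold-change gate, so the filter recovers the planted set exactly
— by design, since the target of the test is the filter, not the DE
estimator.

## Numerical and degenerate-input choices

- ppm error is signed, (obs − theo)/theo × 10⁶; tolerance windows convert
  to m/z intervals as [obs/(1+t), obs/(1−t)].
- Envelope offsets in observed spectra are rounded to the nearest integer
  Da relative to the first envelope peak; duplicate offsets aggregate.
- Empty formulas have mass 0 and a trivial isotope pattern; empty
  annotation lists give all-false matrices; an empty candidate enumeration
  warns rather than fails.
- Hit-dedup tie-breaks are total (|ppm|, −score, name), making annotation
  output deterministic and idempotent.
- Problem sizes in the shipped tests and the acceptance script (504
  candidates, ≤ 100 seeds, 66-precursor runs, 6289-gene tables) keep the
  full suite in single-digit seconds while exercising every code path at
  the study's actual scale — the four-condition screen is the study's own
  size.
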