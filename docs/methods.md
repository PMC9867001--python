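# Methods

## Overview

`peptiprospect` models the *in-silico* prospecting of bioactive peptides
(BAPs) from food proteins as three composable stages:

1. **Simulated gastrointestinal digestion** — rule-based cleavage of protein
   sequences by pepsin (pH > 2, EC 3.4.23.1), trypsin (EC 3.4.21.4) and
   chymotrypsin A (EC 3.4.21.1), under two published rule *dialects*
   (`BIOPEP`, `EXPASY`) that encode the same enzymes differently.
2. **A screening funnel** — sequential exclusion of digestion products by
   ingested predictor scores: cytotoxicity, bitterness, plasma and
   intestinal stability, plus allergen-motif and novelty screens.
3. **Consensus shortlisting** — per-bioactivity selection rules combining
   predictor thresholds with receptor active-site binding criteria for the
   enzyme-inhibitory classes (ACE for antihypertensive, DPP-IV for
   antidiabetic peptides).

The package never computes predictor scores or binding models itself; those
are ingested as data. Its contribution is the cleavage-rule grammar, the
funnel accounting, and the consensus rules.

## Digestion model

Cleavage rules use Schechter–Berger window notation: a cut between P1 and
P1' fires when the P1 residue (or, for some rules, the P1' residue) is in
the enzyme's cleavable set, unless a *blocking pattern* over positions
P4…P2' matches. Blocking patterns can themselves be re-enabled by
*override* patterns (e.g. trypsin's P1'=P block is lifted in W-K-P and
M-R-P contexts). Window positions outside the sequence never match, so an
out-of-range blocker cannot block.

Co-digestion is **simultaneous and exhaustive**: the cut-site sets of all
enzymes of one dialect are unioned and the sequence is split at every site.
This mirrors a single multi-enzyme run on either source platform; partial
digests, missed cleavages, enzyme kinetics and conformational shielding are
out of scope. Coordinates are 0-based half-open; a cut at position *i*
separates residues *i−1* and *i*.

Rule sets live in editable YAML data files (`data/rules_*.yaml`), one per
dialect, and user-supplied files in the same schema are accepted.
Noteworthy encoding decisions:

* **BIOPEP trypsin** blocks only K-P, not R-P — implemented verbatim as the
  dialect states it, although common trypsin rules block both. The EXPASY
  dialect blocks both (with the overrides above).
* **EXPASY chymotrypsin (low specificity)** lists F/Y/W/L/M as cleavable
  but also states blocking contexts for H at P1; H is therefore included in
  the P1 set by default (otherwise that exception could never fire), with
  `chymotrypsin_h_at_p1=False` restoring the strict five-residue reading.
* **EXPASY pepsin (pH > 2)** is published only as "broad specificity with
  preference at F, Y, W, L in position P1 or P1'". The shipped matrix is a
  transcription of the PeptideCutter positional table: cleavage when
  F/L/W/Y sits at P1 or P1', blocked by P at P2/P1'/P2', by H/K/R at P1
  when the hydrophobic driver is at P1', and by R at P3 when the driver is
  at P1. The matrix is data, not code, precisely so it can be corrected if
  a discrepancy against platform output is found; no offline validation
  against the platforms' own full-proteome totals is possible from within
  this repository (sequences are not bundled, see below).

### Idempotence and its limits

Re-digesting a produced fragment returns the fragment unchanged whenever
every exception of the rule set stays inside the P1/P1' window — true for
the whole BIOPEP dialect. It is *not* universally true for EXPASY:
exceptions there consult P2/P3/P2' context that a neighbouring cut can
sever. Example: in `…ARRHA…` trypsin blocks R|H because R sits at P2, but
that arginine is itself a cut site; the liberated fragment `RHA` re-digests
to `R|HA`. This is an inherent property of single-pass platform semantics,
not an implementation artifact; the engine digests the *parent* sequence
authoritatively (as the platforms do) and the behaviour is pinned by a
dedicated test. `fragment_consistency` deliberately uses fragment-local
judgment — blockers reaching outside the fragment are unknown and treated
as non-blocking — making it a conservative plausibility check for claimed
digestion products.

## Screening funnel

The four default threshold filters, with boundary semantics chosen to
match the stated criteria literally:

| stage | field | rule | boundary |
|---|---|---|---|
| toxicity | SVM score | exclude if > 0.0 | 0.0 is non-toxic |
| bitterness | scoring-card score | exclude if > 333 | 333 is non-bitter |
| plasma stability | half-life (s) | keep if ≥ 800 | 800 s is kept |
| intestinal stability | half-life (s) | keep if > 1.0 | 1.0 s is removed |

Filters are conjunctive, so the survivor *set* is order-invariant; order
only attributes exclusions to stages. Records missing a referenced score
are quarantined, never silently kept. The allergen screen reports both
containment directions (motif inside peptide; peptide inside motif); the
shipped epitope file is an explicitly empty placeholder because no epitope
list is distributed with the package — supply one to make this screen
exclusionary. Novelty is an exact-sequence lookup against local plain-text
collections; nothing is queried live.

## Consensus rules

Default per-class rules (all thresholds configurable):

* **AHP** — AHTpin > 1.0 *and* predicted contact with all three ACE
  zinc-site residues {H383, H387, E411} (PDB 1O86); when human intestinal
  absorption and bioavailability scores are supplied, HIA < 30 % and
  bioavailability < 20 % are additionally applied (skipped with a warning
  otherwise). Ranked by AHTpin.
* **ADP** — scoring-card score ≥ 350 *and* contact with ≥ 2 of the DPP-IV
  catalytic triad {S630, D708, H740} (PDB 2ONC). The ≥ (not >) bound is
  deliberate: a peptide scoring exactly 350 is selectable. Ranked by score.
* **AIP** — positive by both anti-inflammatory predictors, top 4 by PreAIP.
* **AMP** — CAMP-SVM = 1 ∧ CAMP-RF > 0.54 ∧ ADAM > 2, with
  platform-positive peptides (DBAASP) appended. When no ADAM score is
  supplied the predicate is skipped by default (`adam_missing_policy=
  "ignore"`); `"strict"` demands it.
* **ACP** — positive cross-hits of all three anti-cancer predictors, top 3
  by mACPpred.

Positivity is an explicit flag column when the score table provides one,
else score > 0.5. Ties in ranking break lexicographically, so selections
are deterministic and invariant to input order. Raising any threshold can
only shrink a selection (monotonicity; property-tested).

A known anomaly of the reference tables is preserved as documentation, not
reproduced: one published antihypertensive selection (QQQIK) contacts only
one of the three ACE active-site residues and therefore fails the stated
full-binding criterion; the default rule follows the criterion.

## Descriptors

`descriptors()` reports length, amino-acid and dipeptide composition
fractions, integer net charge (+1 K/R, −1 D/E, histidine neutral — a
documented simplification), hydrophobic fraction over a configurable set
(default A/V/I/L/M/F/W/C, the Kyte–Doolittle-positive residues), terminal
residues with class tags (aromatic {F,W,Y}, branched {V,L,I}, positively
charged {K,R,H}, proline), and proline/cysteine counts. Amphiphilicity
moments, secondary structure and isoelectric points are out of scope.

## Packaged data and synthetic generation

The package ships, as tab-separated text validated at load time: the
151-row screened candidate long list, the shortlist score table (with
explicit positivity flags where the published calls sit below the generic
0.5 reading), the ACE and DPP-IV binding reports (9 and 7 peptides), and
the 13-protein catalogue (accessions and metadata only). Protein
*sequences* are not bundled; `io.fetch_reference_proteome` retrieves them
by accession when network access is available, which the full-proteome
reproduction test requires.

The synthetic generator draws proteins from a configurable residue
frequency profile and attaches scores from normal anchors spanning the
realistic ranges of the packaged table (toxicity ≈ −0.8, bitterness ≈ 300,
plasma half-life ≈ 835 s, intestinal ≈ 1.5 s), clamped to the passing side
of every default threshold unless a record is deliberately *planted* to
fail a named filter — so funnel tests have exactly known expected outcomes.
It does not emulate real residue usage, score correlations, or any
sequence–score relationship; passing synthetic tests therefore validates
the machinery, not predictor realism. All randomness flows through one
seeded generator.

An independent digestion oracle (naive per-position lookup against its own
literal rule tables, sharing no code with the engine) backs the
equivalence property tests: engine ≡ oracle on 1000 seeded random
sequences per dialect, with reassembly asserted throughout.

## Problem sizes

Property tests use 1000 random sequences per dialect (lengths 2–30) for
oracle equivalence, 300 for reassembly/idempotence, and synthetic funnels
of ~65–100 candidates; the acceptance script uses 500 sequences per
dialect plus a five-protein synthetic proteome (~300 residues each). These
sizes give stable statistics while keeping the default run fast.
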