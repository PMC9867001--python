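# peptiprospect

In-silico prospecting of bioactive peptides (BAPs) from gastrointestinally
digested food proteins — built around the discovery funnel used for marine
and other dietary protein sources such as Pacific oyster (*Crassostrea
gigas*).

Short protein fragments (2–20 residues) released by digestive proteases can
carry antihypertensive, antidiabetic, anti-inflammatory, antimicrobial or
anticancer activity. Finding them experimentally is slow; this package
implements the computational side of the hunt:

* **Digestion** — exhaustive simultaneous cleavage by pepsin (pH > 2),
  trypsin and chymotrypsin A, under two rule *dialects* (`BIOPEP`,
  `EXPASY`) reflecting how the two public hydrolysis platforms encode the
  same enzymes. Rules are Schechter–Berger positional grammars (cleave
  C-terminal to P1 ∈ {K, R}, blocked when P1' = P, overridden in W-K-P
  contexts, …) stored as editable YAML data.
* **Screening funnel** — sequential exclusion filters over ingested
  predictor scores: toxic if SVM score > 0.0; bitter if score > 333;
  kept if plasma half-life ≥ 800 s and intestinal half-life > 1.0 s; plus
  allergen-motif and exact-sequence novelty screens. Stage-by-stage
  accounting, quarantine for unevaluable records.
* **Consensus shortlisting** — per-bioactivity rules combining predictor
  cutoffs with receptor active-site criteria, e.g. antihypertensive
  candidates must contact all three ACE zinc-site residues
  {H383, H387, E411}; antidiabetic candidates need score ≥ 350 and ≥ 2 of
  the DPP-IV catalytic triad {S630, D708, H740}.
* **Descriptors** — composition, net charge, hydrophobic fraction and
  terminal-residue classes for trend analysis of shortlisted peptides.
* **Fixtures & synthetic data** — the published 151-peptide screened long
  list, shortlist scores and binding tables ship as validated TSV; seeded
  generators produce proteins and score tables (with plantable filter
  failures) so every stage is testable offline.

## Worked example

```python
>>> import peptiprospect as pp

# digest a toy protein under the ExPASy dialect
>>> specs = pp.compile_ruleset("EXPASY")
>>> [f.sequence for f in pp.codigest("MKVLAAKPAWRTS", specs)]
['M', 'K', 'V', 'L', 'AAKPAW', 'R', 'TS']

# the K|P bond survives (proline blocks trypsin) and A|W survives (proline
# at P2 blocks the pepsin rule); W|R is cut by chymotrypsin

# run the packaged long list through the screening funnel
>>> longlist = pp.load_fixture("table2_longlist")
>>> survivors, report = pp.run_funnel(longlist, pp.default_filters())
>>> len(survivors)
151
>>> max(r.plasma_half_life_s for r in longlist)
1058.51

# antidiabetic consensus: score >= 350 and >= 2 catalytic-triad contacts
>>> scores = pp.load_fixture("table3_scores")
>>> bindings = pp.load_fixture("table5_dppiv_bindings")
>>> rules = {r.name: r for r in pp.default_rules()}
>>> pp.select_class(scores.peptides, scores, bindings, rules["ADP"])
['EQTQP', 'YPPVHDNN', 'VAPEEHPVL', 'NSPAM', 'SVPVL']
```

All 151 packaged candidates clear the four thresholds (the long list is by
construction the post-screen set); the antidiabetic selection returns the
five peptides that both score ≥ 350 and contact at least two of S630,
D708, H740 — ranked by score, deterministic ties.

A command-line umbrella mirrors the library:

```bash
peptiprospect simulate --seed 7 --out sim/          # synthetic FASTA + scores
peptiprospect digest --fasta sim/proteome.fasta --dialect both --out dig/
peptiprospect screen --candidates sim/candidates.tsv --out scr/
peptiprospect shortlist --out short/                # packaged fixtures by default
```

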