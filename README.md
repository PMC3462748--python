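# barnapep

In-silico neuropeptidome discovery for the barnacle *Balanus amphitrite*
(and similar non-model arthropods), plus the statistics that accompany such
a catalog. The package is aimed at comparative endocrinologists and
biofouling researchers who have a transcriptome assembly and a set of known
arthropod peptides, and want a reproducible, fully scriptable version of
the classical discovery workflow:

1. **Mine** — align reference peptides against all six frame translations
   of every transcript with exact affine-gap Smith–Waterman, scoring
   significance with the Karlin–Altschul formula
   E = K·m·n·e^(−λS) (λ = 0.267, K = 0.041, gapped BLOSUM62); keep the top
   k hits per query below E < 0.01.
2. **Screen** — extract the stop-to-stop ORF around each hit and apply the
   three precursor criteria: a signal peptide (hydrophobic core +
   (−3,−1) small-residue rule), at least one prohormone processing site,
   and length < 300 aa.
3. **Process** — predict convertase cleavage (dibasic KR/RR; monobasic Arg
   with a basic at −4/−6/−8; multibasic runs; no cleavage before Pro),
   excise the mature peptides, and flag C-terminal amidation (Gly donor),
   N-terminal pyroglutamate and acidic-context Tyr sulfation.
4. **Annotate** — assign peptide families from terminal motifs
   (FGLamide ASTA, W(X6)Wamide ASTB, SIFamide, sulfakinin
   [YF]G[HMF][MLF][RK]Famide, orcokinin NFDEIDR, ...), align family members
   (Needleman–Wunsch and a centre-star progressive MSA).
5. **Quantify** — 2^-ΔΔCt developmental expression with a reference gene
   and one-way ANOVA/Tukey HSD across stages, and arcsine-√p ANOVA/Tukey of
   settlement bioassay counts.

Because the study's raw data are unpublished, a first-class synthetic-data
module generates every input with known ground truth — planted precursors,
decoy transcriptomes, Ct tables and binomial settlement counts — and a
synthetic reconstruction of the published peptide catalog (16 families,
64 mature peptides) ships in `barnapep.catalog`. See `docs/methods.md` for
the model details and what the synthetic data do and do not emulate.

## Worked example

Plant three precursor families among 100 decoy transcripts, mine with
synthetic "related-species" homolog queries, and run the full discovery:

```python
import numpy as np
from barnapep.catalog import discovery_specs
from barnapep.simulate import generate_transcriptome, homolog_query
from barnapep.pipeline import run_discovery, assigned_family

specs = [s for s in discovery_specs() if s.family in ("PDH", "SULF", "TRP")]
transcripts, truth = generate_transcriptome(specs, n_decoys=100, seed=42)
rng = np.random.default_rng(43)
queries = [homolog_query(truth.planted[f"planted_{s.family}"], rng)
           for s in specs]
aps, manifest = run_discovery(transcripts, queries)
print(manifest.stage_counts)
for ap in aps:
    print(ap.candidate.transcript_id, assigned_family(ap, queries),
          [p.display for p in ap.peptides])
```

prints (stage counts, then one line per screen-passing precursor):

```
{'transcripts': 103, 'queries': 3, 'hits': 4, 'candidate_transcripts': 3,
 'candidates': 3, 'screened': 3, 'reported': 3}
planted_PDH PDH ['HTNSLHDEHT', 'NSELINSLLGLPKIMNEA-NH2']
planted_SULF SULF ['ELSTTEHNLN', 'pQFDDYGHMRF-NH2', 'AADEYGFMKF-NH2',
                   'GGEEYGMLKF-NH2', 'SLDDYGFFKF-NH2']
planted_TRP TRP ['LHHTAESLSS', 'APSGFLGMR-NH2', 'APSGFFGMR-NH2',
                 'SSSGFLGMR-NH2', 'APQGFYGVR-NH2']
```

All three planted families are recovered and no decoy passes the screen.
The first peptide on each precursor is its propeptide spacer (no family
motif); `-NH2` marks Gly-donor amidation and `pQ` an N-terminal
pyroglutamate. The pigment-dispersing-hormone mature peptide is the
expected `NSELINSLLGLPKIMNEA-NH2`.

Expression profiling on a simulated Ct table with a planted 6-fold cyprid
effect:

```python
from barnapep.simulate import generate_ct_table
from barnapep.quant import ddct, stage_anova

df = generate_ct_table({"sif": {"NauVI": 2.0, "Cyp": 6.0, "Juv": 1.0,
                                "Adu": 0.5}}, seed=7)
fc = ddct(df, "cytb", "Juv")["sif"]
print({s: round(f, 2) for s, f in fc.fold.items()})
res = stage_anova(fc)
print(f"F({res.df_between},{res.df_within}) = {res.f_statistic:.1f}, "
      f"p = {res.p_value:.2g}")
```

```
{'NauVI': 1.97, 'Cyp': 5.38, 'Juv': 1.0, 'Adu': 0.55}
F(3,32) = 121.3, p = 1.5e-17
```

The planted folds (2, 6, 1, 0.5) are recovered within noise and the
cyprid-vs-juvenile contrast is Tukey-significant.

The same workflow is available from the shell:

```sh
barnapep simulate-transcriptome --decoys 500 --seed 1 --out tx.fasta
barnapep discover tx.fasta.queries.fasta tx.fasta --out report.tsv
barnapep qpcr ct_table.tsv --out folds.tsv
barnapep assay wells.tsv --out assay.tsv
```

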