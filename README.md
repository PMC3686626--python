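# fpbench

A benchmarking platform for 2D-fingerprint **ligand-based virtual
screening** (VS). Given a target's known actives and presumed inactives
(decoys), a similarity-search method ranks a test library by similarity to
a handful of query actives; `fpbench` measures how well different molecular
fingerprints perform at this task, and whether the observed differences are
statistically meaningful.

The experiment is a three-stage pipeline:

1. **Scoring** — for each of *R* repetitions (default 50), a training list
   selects query actives (default 5) and held-out training decoys (default
   20%); every remaining test molecule is scored by its *maximum* Dice
   similarity to the queries (MAX fusion) and the test set is ranked.
2. **Validation** — each ranked list is evaluated with
   - AUC, the area under the ROC curve: the fraction of (active, inactive)
     pairs ranked correctly, `0.5` = random;
   - EF(χ) = `Σᵢ δ(rᵢ ≤ χN) / (χn)`, the enrichment factor in the top
     fraction χ (maximum `1/χ` when `χ ≥ n/N`);
   - RIE(α) = `Σᵢ e^(−αrᵢ/N)` divided by its analytic random average
     `(n/N)(1−e^(−α))/(e^(α/N)−1)`;
   - BEDROC(α) = `(RIE − RIE_min)/(RIE_max − RIE_min)`, the [0, 1]-bounded
     form of RIE;

   where `n` is the number of test actives, `N` the test-set size and `rᵢ`
   the rank of the *i*-th active. Within each repetition the fingerprints
   are ranked by their score (rank 1 = best, ties averaged).
3. **Analysis** — per-target average performance, average fingerprint
   ranks across targets, a tie-corrected global Friedman test
   (targets as blocks), and — when it is significant — all-pairs post-hoc
   comparisons: the 50 repetition ranks are bootstrap-resampled 100 times,
   each replicate's pairwise p-values are multiplicity-adjusted with a
   Westfall–Young maxT sign-flip resampling scheme, and each pair is
   called `-` (all 100 adjusted p < 0.05), `X` (all ≥ 0.05) or `o` (mixed).

Fourteen built-in fingerprints (computed with RDKit) cover three
descriptor classes: MACCS keys; the path-based AP, TT, RDK5, Avalon and
lAvalon; and the circular ECFP4/6, lECFP4/6, FCFP4, ECFC4, FCFC4 and the
atom-count baseline ECFC0. Bit strings use 1024 bits (16384 for the
`l`-variants); supported similarity measures are Dice (default), Tanimoto,
Cosine, Russel, Kulczynski, McConnaughey, Manhattan and Rogot–Goldberg.
Scaffold-hopping is probed with Bemis–Murcko scaffolds and the scaffold
enrichment factor.

Because the public MUV / DUD / ChEMBL benchmark collections cannot be
redistributed here, the package ships a **synthetic fixture generator**
that emulates their shapes (diverse actives among many decoys; analog
series with property-matched decoys; diverse actives with two
atom-count-matched decoys each) from an internal template library, with a
`difficulty` knob controlling how strongly decoys overlap the active
scaffolds. It also implements the curation operators used to build such
collections: MaxMin diversity picking, decoy selection by ECFC0 Dice
similarity > 0.5, and removal of molecules > 700 g/mol or containing
metals.

## File formats

Compound list (`.smi`-style text, whitespace-separated, `#` comments,
gzip-transparent). Internal IDs are
`<dataset>_<targetID>_<A|D>_<number>` with `A` = active, `D` = decoy and
0-based numbering in file order:

```
# external_id internal_id smiles
EXT-A0 SYNDUD_T1_A_0 CC(=O)NCc1cnc(-c2ccc3ccccc3c2)[nH]1
EXT-A1 SYNDUD_T1_A_1 FC(F)(F)Cc1ccc(-c2ccncc2)o1
```

Training list (JSON lines, one repetition per line, `(internal_id, index)`
pairs):

```
{"repetition": 0, "query_actives": [["SYNDUD_T1_A_2", 2], ...], "training_decoys": [["SYNDUD_T1_D_0", 0], ...]}
```

Scored lists (JSON lines of `(similarity, internal ID, active flag)`) and
all analysis outputs (CSV) are plain text as well, so ranked lists from
other tools can enter the pipeline at the validation stage.

## Worked example

```sh
cat > recipe.json <<'EOF'
{"style": "DUD-like", "n_actives": 20, "n_decoys": 100, "n_series": 5,
 "difficulty": 0.4, "seed": 0, "repetitions": 10, "n_queries": 5}
EOF
printf 'ECFP4\nTT\nMACCS\nECFC0\n' > fps.txt
printf 'AUC\nBEDROC 20\nEF 0.05\n' > methods.txt

fpbench fixtures -c recipe.json --n-targets 4 --seed 42 -o data
fpbench score    -f fps.txt -n 5 -s Dice -i data -o scored.jsonl --seed 42
fpbench validate -m methods.txt -i scored.jsonl -o values.csv
fpbench analyze  -i values.csv -o analysis --seed 42
```

`analysis/average_rank.csv` then contains the mean rank of each
fingerprint across the 4 targets (lower is better):

```
,ECFP4,TT,MACCS,ECFC0
AUC,1.925,1.875,3.375,2.825
BEDROC(20),1.925,1.975,2.825,3.275
EF(0.05),2.200,2.350,2.6375,2.8125
```

On these analog-series fixtures the high-resolution fingerprints (ECFP4,
TT) are consistently ranked ahead of the two baselines (MACCS, ECFC0), and
`analysis/friedman_global.csv` shows the effect is strongest for the
early-recognition metric:

```
method,statistic,p_value
AUC,6.846,0.0770
BEDROC(20),8.100,0.0440
EF(0.05),3.462,0.3258
```

With only 4 synthetic targets the post-hoc pairwise calls in
`analysis/category_matrix_BEDROC(20).csv` remain `X` (no pair separates
with all 100 adjusted p-values below 0.05) — separating fingerprint pairs
reliably takes many more targets, which is exactly what the significance
machinery is there to guard against.

The same steps are available as library calls (`fpbench.generate_target`,
`score_target`, `evaluate`, `friedman_global`, `posthoc_pairwise`, ...);
see `docs/methods.md` for the statistical details and design choices.

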