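# mirpath

Rank microRNAs by how strongly their target genes are over-represented in a
curated set of disease-relevant pathways — without any expression data.
The package is aimed at systems-biology groups doing exploratory candidate
screening before wet-lab validation: given only pathway gene sets (with
curator-assigned relevance classes), a transcription-factor edge table, and
miRNA→target annotations, it produces a single significance score per miRNA
and a shortlist of candidates at a strict threshold.

## Method

For each miRNA *m* and each pathway *P* (first extended with the upstream
TFs of its member genes, since miRNAs often act on a gene through its
regulators), a 2×2 contingency table is built over the *target universe*
*U* — the union of all miRNAs' target sets:

|                | in pathway | not in pathway |
|----------------|-----------:|---------------:|
| targeted       | Np⁺ = \|T ∩ P\| | Nm⁺ − Np⁺ |
| not targeted   | Np⁻ = \|P\| − Np⁺ | Nm⁻ − Np⁻ |

with Nm⁺ = |T|, Nm⁻ = |U| − |T|, and P restricted to U so genes never
annotated as anyone's target do not dilute the test.  Enrichment is the
one-tailed Fisher exact test, i.e. the hypergeometric upper tail
P(X ≥ Np⁺).

Per miRNA, the pathway p-values are Benjamini–Hochberg adjusted and then
combined with Lancaster's weighted generalization of Fisher's combined
probability test:

  T = Σᵢ F⁻¹_{χ²(wᵢ)}(1 − pᵢ),

where the weight wᵢ encodes the pathway's relevance class (A → 2, B → 1,
C → 0.5; realized as Gamma(w/2, scale = 2) so fractional weights are
exact).  With all weights equal to 2 this is exactly Fisher's method.
Because pathways share genes the individual tests are correlated, so the
default null for T is a Brown-style moment-matched scaled chi-square fitted
to permuted pseudo-miRNAs (an explicit permutation p-value is also
available).  miRNAs with combined p < 0.01 (strict) form the candidate
panel; two optional biological filters (tissue expression, intragenic host
genes) narrow the analyzed set, and a random-pathway control replays the
pipeline on random gene sets to check the selection is specific to the
curated list.

## Worked example

`examples/01_simulate_and_enrich.py` simulates a complete study — 39
relevance-classed pathways, 500 miRNAs, 10 of them planted with 5× target
enrichment in three class-A pathways each — and runs the full pipeline:

```
scored 500 miRNAs over 39 pathways (null: moment_matched, effective df 0.57 of nominal 45.5)
17 miRNAs selected at p < 0.01

top 5 by combined p-value (-log10 p is the plotted score):
    1  mir-0005  T= 599.54  p=2.74e-15  -log10(p)=14.56
    2  mir-0003  T= 417.65  p=3.1e-11  -log10(p)=10.51
    3  mir-0010  T= 397.57  p=8.74e-11  -log10(p)=10.06
    4  mir-0001  T= 393.62  p=1.07e-10  -log10(p)=9.97
    5  mir-0008  T= 381.75  p=1.98e-10  -log10(p)=9.70

planted-miRNA recovery: 100% of the 10 planted miRNAs rank in the top decile
```

T is the Lancaster sum, p its upper-tail probability under the
moment-matched null, and −log10(p) the score conventionally plotted for
ranked candidates.  All ten planted miRNAs land in the top decile; the
effective degrees of freedom (0.57, far below the nominal Σwᵢ = 45.5)
show how strongly the BH step and inter-pathway correlation compress the
null distribution of T — ignoring that (the "independent" null) misstates
significance.

The other examples demonstrate null calibration
(`02_null_calibration.py`: 3/500 ≈ 0.6% selected with no signal, near the
nominal 1%), the random-pathway control (`03_random_control.py`: 17
selected on the planted list vs 7 on random pathways), and the two
membership filters (`04_filters.py`).

## Command line

For file-based runs there is a thin CLI over the same library code:

```sh
mirpath simulate --scenario scenario.yaml --out fixtures/
mirpath enrich   --config run.yaml
mirpath control  --config run.yaml --pool fixtures/pathways.gmt --k 39
```

`enrich` writes per-pair and per-miRNA TSVs plus a JSON manifest (config
echo, input hashes, seed, drop counts) so runs are auditable and
byte-reproducible.

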