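# duotune

Synthetic-data generation and noise analysis for **dual, independently
tunable, low-noise bacterial gene expression systems** — bicistronic
circuits in which a repressor (TetR- or LacI-style) and a gene of interest
are translated from one mRNA whose promoter the repressor represses, carried
on compatible plasmid backbones (p15A-like and pSC101-like) and induced with
ATc or IPTG.

It is aimed at people who quantify cell-to-cell expression variability
("noise") from flow cytometry or fluorescence microscopy and want a tested,
reproducible implementation of the standard low-noise analysis pipeline
together with a generator of realistic synthetic data to validate it on.

## What it computes

Noise is the squared coefficient of variation of single-cell fluorescence,

    CV² = σ² / μ²,

with μ and σ² estimated not from raw moments but by the robust procedure
used in this field:

1. **Density gating** — retain the third of events nearest the mode of the
   2D (log FSC-area, log SSC-height) histogram, selecting typical-size cells.
2. **Log-binned density estimation** — estimate the probability density of
   the fluorescence channel on bins spaced equally in log.
3. **Gamma fitting** — least-squares fit of a gamma density
   Gamma(k, θ) to the binned estimate; then μ = kθ, σ² = kθ², and the
   fitted law's CV² = 1/k. The fit strongly discounts low-fluorescence
   stragglers that escape gating.
4. **Background subtraction** — the fitted mean of an autofluorescence-only
   control strain is subtracted from each sample's fitted mean.

The synthetic generator models the circuit mechanistically: per-copy
promoter activity `a(R) = basal + (1−basal)/(1 + (R/K_R)^h)`, inducer
de-repression `ρ(I) = 1/(1 + (I/Kd)^h_I)`, and — in the autoregulated mode —
the feedback fixed point `G = N·α·a(r·G·ρ(I))` per cell with plasmid copy
number N, followed by gamma-distributed intrinsic (burst) noise and a
multiplicative lognormal cell-size factor. Negative autoregulation makes
mean expression scale sub-proportionally with copy number (dosage
compensation), which is why moving the circuit to a lower-copy backbone
costs much less expression than it would without feedback.

A companion microscopy module renders cells as rod masks with diffuse
fluorophore concentration and optional single-mRNA spots (24 tandem PP7
coat-protein sites, dimeric binding, up to 48 fluorophores per
diffraction-limited spot), quantifies them by the mask-based
background-subtracted mean-intensity protocol, and scores spot
detectability (SNR) against the shot noise of unbound fluorescent protein.

## Worked example

Run the default characterization — the 10-dose IPTG ladder (0, 2, 4.5, 10,
22.4, 50, 111.8, 250, 559, 1250 μM), 3 replicates, 30,000 events per sample,
one-third gate:

```python
from duotune import RunConfig, run_pipeline
from duotune.expression_metrics import dose_response
from duotune.cli import _frame_to_summaries

frame, log = run_pipeline(RunConfig())
print(frame.groupby("condition_iptg_uM")[["mean_bgsub", "cv2"]].mean().round(4))
dr = dose_response(_frame_to_summaries(frame), inducer="iptg")
print(f"dynamic range (nonzero IPTG): {dr.dynamic_range:.1f}-fold")
```

prints

```
                   mean_bgsub     cv2
condition_iptg_uM
0.0                  282.2332  0.0991
2.0                  283.8830  0.1028
4.5                  282.7259  0.1013
10.0                 282.4211  0.1005
22.4                 303.8163  0.0963
50.0                 480.9487  0.0812
111.8               1301.6602  0.0719
250.0               3813.7677  0.0709
559.0               9162.7864  0.0887
1250.0             13415.6697  0.1223
dynamic range (nonzero IPTG): 47.5-fold
```

`mean_bgsub` is the background-subtracted mean fluorescence (AU): flat at
low IPTG where feedback holds the circuit near its basal fixed point, then
rising ~47-fold to saturation. `cv2` is the expression noise: near the
~0.1 extrinsic noise limit at every dose — the low-noise signature of
bicistronic autoregulation — with a mild rise at full induction where the
feedback is released and plasmid copy-number variation passes through.

The same analysis is available from the shell:

```bash
duotune run --out results/run            # whole pipeline, default config
duotune gate --in events.csv --fraction 0.3333 --out gated.csv
duotune fit  --in gated.csv --column fl1_area --out fit.json
```

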