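# wscec — ECG heartbeat classification by Wasserstein scalar curvature

`wscec` classifies single-lead ECG heartbeats by a geometric feature of
their local signal structure.  It is aimed at researchers in biomedical
signal processing who want an interpretable, training-free alternative to
learned classifiers for arrhythmia screening (normal beats, atrial
premature beats, ventricular abnormalities, bundle branch block).

## Method

A 300-sample heartbeat `T` at 360 Hz is processed in four stages:

1. **Embedding.**  Sliding windows of length `l = 10` (step `τ = 1`) are
   mapped to their leading DFT coefficients
   `(2/l)·(a₀, a₁, b₁)` with `C_k = a_k + i b_k = Σᵢ tᵢ e^{-2πiki/l}`,
   producing an ordered point cloud of 289 points in `R³`.
2. **Local statistics.**  Each point receives its `k = 20` nearest
   neighbours; their unnormalised scatter matrix
   `Σᵢ = Σⱼ (Nᵢⱼ − μᵢ)ᵀ(Nᵢⱼ − μᵢ)` lifts the cloud onto the manifold
   SPD(3) of symmetric positive-definite matrices.
3. **Curvature.**  SPD(n) carries the Bures–Wasserstein metric
   `g_W|_S(X, Y) = ½ tr(Γ_S[Y] X)`, where `Γ_S[Y]` solves the Sylvester
   equation `SΓ + ΓS = Y`; its geodesic distance is the L2
   optimal-transport distance between centred Gaussians,
   `W² = ‖Δμ‖² + tr(Σ₁ + Σ₂ − 2(Σ₁^{1/2} Σ₂ Σ₁^{1/2})^{1/2})`.
   The scalar curvature `ρ(S)` — a closed form in the spectrum of `S`,
   validated against a brute-force basis sum of the curvature tensor —
   is evaluated at every scatter matrix, giving the curvature sequence
   `W = {wᵢ}`.  It obeys `0 < ρ(S) < 3n(n−1)/λ_min2(S)`, so curvature is
   controlled unless a scatter degenerates in two or more directions.
4. **Dispersion and diagnosis.**  `W` is binned into a histogram with
   width `m = 1` and ceiling `b = min(max ρ of a standard normal beat,
   3d(d−1)/ε)` (with `ε = 0.09`, the cap is 200).  The feature is the
   dispersion pair: `cur1` = median of the in-range curvatures
   (transverse dispersion, tracking QRS width) and `cur2` = a corrected
   standard deviation of the column heights that grows when columns are
   empty (longitudinal dispersion, tracking QRS fluctuation).  A
   rectangular partition of the `(cur1, cur2)` plane — e.g. normal =
   `(25, 200] × [0, 25]` — yields the diagnosis.

Narrow, regular QRS complexes spread curvature mass evenly (large
`cur1`); widened or erratic complexes concentrate it low (small `cur1`,
larger `cur2`).

## Worked example

The synthetic generator produces beats with class-specific PQRST
morphology, so the whole pipeline runs without any data download:

```python
from wscec import BeatSpec, generate_beat, run_wscec

std = generate_beat(BeatSpec("N", noise_sd=0.0, seed=0))
beats = [generate_beat(BeatSpec(c, seed=10 + i))
         for i, c in enumerate(["N", "N", "L.B.B.B.", "A.P.", "V.F."])]
result = run_wscec(beats, std)
print("histogram ceiling b =", result.b)
print(result.feature_table()[["beat_id", "label", "cur1", "cur2", "coarse"]])
```

prints

```
histogram ceiling b = 200.0
 beat_id    label       cur1     cur2 coarse
       0        N 139.417271 1.702255 normal
       1        N 110.734251 1.661266 normal
       2 L.B.B.B. 107.267512 1.655734 normal
       3     A.P. 126.225278 1.454424 normal
       4     V.F.  37.264729 3.922100 normal
```

The ceiling is the analytic cap `3·3·2/0.09 = 200`.  The transverse
dispersion `cur1` orders the beats the way the theory predicts: largest
for the regular normal beats, smaller for the widened-QRS L.B.B.B. beat
and smallest for the near-sinusoidal ventricular flutter.  The `coarse`
column applies the default domain partition, which is calibrated for
MIT-BIH-style recordings; for synthetic data the absolute box positions
do not transfer (the flutter beat's dispersion falls inside the normal
box), so a recalibrated partition can be supplied as JSON via
`PipelineConfig(partition=DomainPartition.from_json(path))` — the
*ordering* of the classes is what the synthetic conditions reproduce.

A command-line interface mirrors the library:

```bash
wscec synth --classes N:30,L.B.B.B.:10 --seed 7 --out rec/
wscec run --input rec/record.csv --fs 360 --out results/
wscec eval --pred results/features.csv --truth truth.csv
```

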