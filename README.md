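# wavecon

Frequency-resolved functional connectivity from large-scale spike
recordings.

Multielectrode arrays record hundreds of spiking neurons with
sub-millisecond resolution. Pairwise statistical dependencies live on very
different time scales: millisecond-sharp, offset cross-correlogram peaks
(synaptic-like coupling) versus broad zero-centred oscillatory structure
(shared gamma/beta/theta drive). `wavecon` separates these by frequency:

1. **Cross-correlogram** — for each pair (I, J), the binary-state histogram
   C_IJ(τ) = Σ_t i(t)·j(t+τ) at 50 µs (scale 1) or 500 µs (scale 2)
   resolution over a ±70 / ±700 ms window, with near-electrode sorting
   artifacts (< 180 µm pairs) linearly interpolated away.
2. **Wavelet transform** — complex Morlet CWT (ω₀ = 4, Torrence–Compo
   normalization) of each correlogram over 101 log-spaced frequencies
   (20–1000 Hz or 2–100 Hz); power = |W|².
3. **Monte-Carlo significance** — per-frequency power thresholds calibrated
   from Poisson white-noise surrogate correlograms (p = 0.001 as the 100th
   highest of 10⁵ per-frequency maxima at full fidelity), tabulated against
   total spike count 10^k (k = 0.0…6.0) and interpolated in log count.
4. **Networks** — significant power peaks become connections; band
   assignment HFC 100–1000 Hz, gamma 30–80 Hz, beta 12–30 Hz, theta
   4–12 Hz; a peak delayed by more than a quarter Fourier period is a
   *directed* edge; binary band networks are built at matched connectivity
   densities by significance ranking.
5. **Graph statistics** — subsampling-controlled (100-node resamples)
   degree distributions, clustering, efficiency, assortativity, and the
   exponential distance decay P(d) = A·e^(−d/λ) + C of connection
   probability.

A synthetic module generates spike populations with known ground truth
(lognormal rates, hexagonal 60 µm array geometry, synaptic-like delayed
couplings, sinusoidal common drive) so the whole pipeline is testable
end-to-end. See `docs/methods.md` for the model details and assumptions.

## Worked example

The anchor computation of the whole method — the wavelet response of a
σ = 1 ms Gaussian correlogram peak:

```python
import numpy as np
from wavecon.correlogram import Correlogram
from wavecon.wavelet import SCALE1, transform, fourier_period

sigma = 1e-3
g = np.exp(-SCALE1.lags**2 / (2 * sigma**2))
c = Correlogram((0, 1), SCALE1.bin_width, SCALE1.lags, g)
p = transform(c, SCALE1)
i, j = np.unravel_index(np.argmax(p.power), p.power.shape)
print(f"peak: {p.freqs[i]:.1f} Hz at lag {p.lags[j]*1e3:.1f} ms")
print(f"T/sigma = {fourier_period(p.freqs[i])/sigma:.2f}")
print(f"direction boundary = {fourier_period(p.freqs[i])/4/sigma:.2f} sigma")
```

prints

```
peak: 116.3 Hz at lag 0.0 ms
T/sigma = 8.60
direction boundary = 2.15 sigma
```

i.e. a millisecond-wide peak maps to ≈116 Hz (high-frequency band), the
best-matching Fourier period is ≈8.6σ, and a Gaussian peak offset by more
than ≈2.15σ classifies as a directed connection.

End-to-end on synthetic ground truth:

```python
from wavecon.synthetic import make_synaptic_population
from wavecon.significance import calibrate, default_count_grid
from wavecon.pipeline import scale_connections
from wavecon.connectivity import build_band_network
from wavecon.wavelet import SCALE1

rec, truth = make_synaptic_population(n_neurons=40, n_edges=20, seed=301)
table = calibrate(SCALE1, n_reps=2000, p_level=0.005, seed=302,
                  k_grid=default_count_grid(2.0, 4.5, 0.5))
conns = scale_connections(rec, 1, table)
net = build_band_network(conns, "HFC", 20 / (40 * 39 / 2), rec.neuron_ids)
found = {tuple(sorted(c.pair)) for c in net.edges}
print(len(found & truth.pairs("synaptic")), "of", len(found), "edges are true")
```

prints `19 of 20 edges are true` — at matched edge count, the top twenty
high-frequency connections are almost exactly the twenty injected 3 ms
synaptic couplings (95 % precision on this seed).

## Command line

```sh
wavecon simulate  --n-neurons 100 --duration 3600 --n-synaptic 20 \
                  --seed 1 --out-prefix sim
wavecon calibrate --scale 1 --seed 2 --out table.npz
wavecon connect   --spikes sim_spikes.csv --positions sim_positions.csv \
                  --duration 3600 --scale 1 --table table.npz --out edges.csv
wavecon metrics   --edges edges.csv --positions sim_positions.csv \
                  --band HFC --seed 3 --out report.json
```

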