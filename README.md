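# dinolum — quantitative analysis of mechanoluminescent dinoflagellate-laden hydrogels

Dinoflagellates such as *Pyrocystis lunula* emit flashes of blue light
(~470 nm) when mechanically stressed. Embedded in soft hydrogels, they turn
the gel into a living mechano-optical transducer: the gel luminesces only
when compressed above a minimum strain **and** strain rate, which makes it
usable as a self-powered force sensor. `dinolum` implements the complete
quantitative tool-chain for characterising such living gels, for
researchers analysing compression videos, mechanical test records and
single-colony emission spectra:

- **Flash counting** (`dinolum.flashcount`) — per-frame luminescent-cell
  counts and total intensity from dark-room RGB video: blue-channel
  extraction, sample masking, a 70/255 noise threshold subtracted with
  clipping, trapezoidal intensity integration, local-maxima cell
  detection, and de-duplication via the pixel-wise maximum projection.
- **Mechanics** (`dinolum.mechanics`) — effective strain rate as the
  maximum point rate (dxᵢ − dxᵢ₋₁)/(tᵢ − tᵢ₋₁) over the loading phase
  (testing machines cannot reach high nominal speeds over short travel),
  engineering stress–strain curves σ = F/(π r²), ε = d/h₀, and the elastic
  modulus from a linear fit in the 1–3 % strain window.
- **Spectroscopy** (`dinolum.spectro`) — time-integration of windowed
  photon-count series (125 ms bins), multi-Gaussian deconvolution of the
  three-peak emission spectrum, Kohlrausch (stretched-exponential) decay
  fitting I(t) = I₀ exp[−(t/τ)^α], detected-to-emitted photon conversion
  through the detector transmission QE·10^(−loss_dB/10), and peak-splitting
  conversion to vibrational wave numbers (1 eV = 8065.54 cm⁻¹).
- **Depletion model** (`dinolum.depletion`) — photon yield vs strain rate
  with luciferin-pool exhaustion: per cycle Eₖ = Pₖ·y·L(rₖ) with a logistic
  activation L rescaled to L(0)=0 and pool update Pₖ₊₁ = Pₖ − Eₖ; forward
  simulation and nonlinear least-squares fitting.
- **Sensor decoding** (`dinolum.sensor`) — pillar-array ("taxel") force
  sensor: per-pillar ROI traces, onset detection at 5× the baseline noise
  SD, video-to-force synchronisation anchored at the 2 % minimum actuation
  strain of the tallest pillar, and force-interval readout from a
  per-pillar onset-force calibration.
- **Synthetic data** (`dinolum.synth`) — generators for all three input
  kinds with known ground truth (cell positions and onsets, machine
  acceleration limits and gel stiffness, peak energies and lifetimes, pool
  sizes, pillar heights), so every stage is testable end to end.

File I/O (TIFF/PNG stacks, CSV records and spectra, YAML configs) and a
multi-stage pipeline live in `dinolum.io`; a `dinolum` command-line tool
wraps the stages.

## Worked example

Run the numbered analyses (each is a thin driver over the library and
writes its tables under `results/`):

```sh
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_count_flashes.py
python analysis/03_mechanics.py
python analysis/04_spectroscopy.py
python analysis/05_depletion_fit.py
python analysis/06_sensor_decode.py --seed 0
```

Output (seed 0):

```
found 8 unique cells (true 8), peak simultaneous 4
rate calibration: effective rate saturates at 7.62 mm/s for nominal >= 10
record: eps_max=0.100, sigma_max=2.69 kPa, modulus=27.2 kPa
peaks: 2.6142 / 2.5056 / 2.3513 eV
lifetime tau = 238 ms, stretch alpha = 0.85
splittings: 876 / 1244 cm^-1
recovered pool 50416 photons (true 50000, 0.8% off); half-activation rate 2.99 mm/s
p3: onset at 2.7 mm (design 2.748 mm), 61.6 mN
non-actuated: p5, p6
decoded force interval: [569, inf) mN
```

Reading these numbers: the counter recovers all 8 simulated cells and
their peak simultaneous count; the machine calibration shows the effective
rate saturating far below high nominal rates (finite acceleration over
short travel); the measured 27.2 kPa loading stiffness is the 22 kPa gel
modulus plus the still-unrelaxed dissipative branch; the deconvolved peak
energies land within a few meV of the generator's 2.617/2.51/2.35 eV and
their splittings fall in the vibrational-band range; the window-aware
Kohlrausch fit returns the generator's τ = 238 ms and α = 0.85 exactly;
the depletion fit recovers the luciferin pool within 1 %; and with all
three calibrated indicator pillars lit the decoded force lies above
569 mN.

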