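# trifret

Three-colour ALEX smFRET analysis of chromatin-remodeller sliding kinetics.

Chromatin remodellers such as Chd1 and SNF2h reposition nucleosomes by
translocating DNA at an internal site (SHL2) on the nucleosome. With a donor
(Cy3) and acceptor (Cy5) reporting on the exit side and a second acceptor
(Alexa750) reporting on the entry side of the same nucleosome, alternating
532/638 nm laser excitation (ALEX) lets both sides be watched at once: DNA
is first pulled onto the entry side, and only after a lag `t_lag` does it
begin to shift off the exit side. `trifret` implements the analysis that
turns raw three-channel intensity traces into that kinetic statistic, plus a
synthetic trace generator and a discrete twist-defect model of the DNA
buffering that causes the lag. It is written for single-molecule
biophysicists who want a reproducible, scriptable version of this analysis.

## What it computes

**FRET observables** (after crosstalk correction, per ALEX cycle):

    E_exit  = 1 − I532_Cy3 / (I532_Cy3 + I532_Cy5 + I532_A750)   (all FRET leaving Cy3)
    E_entry = I638_A750 / (I638_Cy5 + I638_A750)                  (Cy5 → A750 transfer)

Corrections remove direct excitation (Cy5 at 532 nm, Alexa750 at 638 nm),
spectral bleedthrough (Cy3→Cy5 channel, Cy5→A750 channel) and
quantum-yield/detection differences; on noiseless data the forward model is
inverted exactly. Correction parameters can be estimated from post-bleach
trace segments.

**Kinetics.** Onsets of the entry-side FRET rise and the exit-side FRET
decrease are found by a two-phase (baseline + ramp) least-squares breakpoint
scan with continuous sub-frame refinement; `t_lag` is their difference. Lag
distributions are fit as single exponentials (closed-form MLE, a
right-censored variant, and a histogram least-squares mode), and the ATP
dependence of the lag rate is fit with the hyperbolic form
`1/t_lag = k_max·[ATP]/(K_app + [ATP])`.

**Buffering model.** A two-stage twist-defect model: the ATPase injects DNA
in ~1 bp steps; segments between the entry SHL2 and the dyad (capacity 2 bp)
and between the dyad and the exit (capacity 3 bp) transiently absorb
injected base pairs, plus a 1 bp defect formed on binding. For a nucleosome
stalled by a single-stranded gap `m` bp beyond the stall site, the
deterministic mode gives the gap-limited probe shifts; a Gillespie mode
simulates injection/relaxation kinetics and yields lag-time distributions.

## Worked example

Simulate 40 molecules at 500 µM ATP (default condition, mean lag 4.9 s),
correct, detect and fit:

```
$ printf 'n_molecules\t40\nseed\t7\n' > sim.txt
$ trifret simulate --config sim.txt --out traces.tsv --manifest manifest.txt \
      --truth truth.tsv --duration 120
wrote 48000 frames for 40 molecules
$ trifret correct --traces traces.tsv --manifest manifest.txt \
      --params corrections.txt --out fret.tsv
wrote 24000 aligned records
$ trifret detect --fret fret.tsv --out events.tsv
{"n_molecules": 40, "n_unconstrained_exit_before_entry": 0, "frac_unconstrained_exit_before_entry": 0.0}
$ trifret fit --events events.tsv --out fit.txt --seed 1
mean lag 4.91 s +/- 0.626 (N = 40, 0 censored)
```

The recovered mean lag (4.91 ± 0.63 s from 40 events) matches the
generator's 4.9 s; the diagnostic line confirms that no molecule showed
exit-side movement before entry-side movement. The buffering model's
gap-limited shifts for a gap 8 bp beyond the stall site:

```
$ trifret buffer-model shifts --m 8
entry_shift	9
dyad_shift	7
exit_shift	4
```

i.e. 9 bp of DNA move past the entry probe, 7 past the dyad and only 4 past
the exit probe — 5 bp are transiently absorbed on the nucleosome.

## Layout

| module | contents |
| --- | --- |
| `trifret.trace_io` | TSV trace tables, manifests, ALEX frame pairing |
| `trifret.synthetic` | ground-truth kinetics sampling and photon-level rendering |
| `trifret.correction` | crosstalk correction, FRET computation, parameter estimation |
| `trifret.detection` | photobleach steps, onset breakpoints, event tables |
| `trifret.kinetics` | exponential lag fits, ATP dependence, FRET histograms |
| `trifret.buffering` | deterministic and stochastic twist-defect model |
| `trifret.cli` | `trifret` command-line interface |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
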