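# tunedev

Modeling and characterization of tunable genetic expression devices.

## The problem

Genetic sensors and logic gates built from fixed parts often end up with
the wrong response function for their host circuit: too much leak, not
enough dynamic range, or a transition point in the wrong place. A
**tunable expression system (TES)** fixes this after assembly: the
coding sequence sits behind a toehold-switch hairpin that blocks
translation, and a separately transcribed **tuner sRNA** opens the
hairpin. Moving the tuner promoter's strength then dials the device's
output level and fold change continuously, without touching the part
itself.

`tunedev` provides, in one package:

- a **mechanistic kinetic model** of the TES (mRNA, sRNA,
  mRNA–sRNA complex, protein; mass-action binding, leak and activated
  translation, decay and dilution), with exact steady states, ODE and
  delay time courses, NOT/NOR-gate extensions, and a ribosome-coupling
  variant (`tunedev.kinetic_model`);
- **stochastic simulation** of the same network: exact SSA and an
  adaptive tau-leaping engine with a hybrid exact fallback at low copy
  number, plus ensemble summaries and distribution-overlap metrics
  (`tunedev.stochastic_sim`);
- the **flow-cytometry characterization pipeline**: deterministic
  density gating on scatter channels, autofluorescence correction,
  conversion to relative promoter units (RPU), histogram intersection
  (`tunedev.cytometry_stats`);
- **response-function fitting**: Hill fits in log space with explicit
  reliability flags, fold-change/dynamic-range device metrics, sensor
  calibration (`tunedev.response_fitting`);
- a **synthetic-data generator** that emulates full characterization
  experiments — event-level fluorescence and scatter, replicate batch
  effects, controls, design variants — with a complete ground-truth
  manifest (`tunedev.synthetic_data`);
- a **command-line interface** with strict config validation and
  reproducible, fully-logged runs (`tunedev.cli`).

See [docs/methods.md](docs/methods.md) for the model equations, the
parameter regimes, and every numerical choice.

## Worked example

Steady states and the tuner's effect on the on/off fold change
(`NOMINAL` is the default weak-binding parameter preset; activities are
in transcripts/min, converted from RPU by a factor of 79):

```python
from tunedev import NOMINAL, steady_state
from tunedev.kinetic_model import fold_change_profile, rpu_to_rnap

params = NOMINAL.with_inputs(u_in=rpu_to_rnap(0.9), u_tun=rpu_to_rnap(0.15))
st = steady_state(params)
print(f"steady state: m={st.m:.2f}  s={st.s:.2f}  c={st.c:.2f}  p={st.p:.1f}")

prof = fold_change_profile(
    NOMINAL,
    u_in_low=rpu_to_rnap(0.002),
    u_in_high=rpu_to_rnap(6.6),
    tuner_grid=(0.06, 1.5, 38.0, 190.0),
)
print(prof.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
```

Output:

```
steady state: m=435.50  s=15.60  c=4.20  p=740.8
 tuner_activity  output_low  output_high  fold_change
            0.1         0.9       2801.6       3294.8
            1.5         1.0       3038.5       3183.9
           38.0         3.5       8948.5       2552.0
          190.0        12.6      31726.0       2508.2
```

Raising the tuner shifts the whole response curve up (both the off and
on outputs grow) while the fold change shrinks monotonically — the
defining trade-off of the device.

### End-to-end on the command line

Generate a synthetic characterization experiment (6 inputs × 6 tuner
levels × 3 replicates, with controls), then analyze it back:

```sh
$ tunedev synth --device tes --n-events 2000 --replicates 3 --seed 11 --out demo/data
2026-10-02 10:12:10 tunedev INFO wrote demo/data/events.csv (216000 events) and manifest.json

$ tunedev analyze --events demo/data/events.csv --device tes --out demo/analysis
2026-10-02 10:12:20 tunedev INFO wrote medians.csv, hill_fits.csv, demo/analysis/metrics.csv

$ head -4 demo/analysis/metrics.csv
tuner_rpu,dynamic_range,dynamic_range_sd,fold_change,fold_change_sd,n_replicates
0.002,3023.1451163048405,359.4006558304625,1882.9826641980471,213.0825055662704,3
0.03,4132.147247380987,417.27158564169247,413.22058509838774,15.596453384248315,3
0.15,9264.466272131593,1086.0404351373954,281.85192360143924,8.29250841143462,3

$ head -4 demo/analysis/hill_fits.csv
tuner_rpu,y_min,y_max,K,n,reliable,message
0.002,4.722713299961808e-31,27938.26766487661,65.99999999999991,0.9342680557429631,False,K = 66 at the edge of the identifiable window
0.03,1.1044360553311211e-29,4458.332913463899,1.5693234027791856,0.9017816614879856,True,
0.15,4.8640037368323455e-26,9234.643546028661,0.5636193828375949,0.995702725540671,True,
```

Every run also writes a resolved `<command>_config.yaml` recording the
seed, all effective settings, and the package version, so any output
directory regenerates itself. The other commands are `simulate`
(ODE/DDE/SSA/tau-leap time courses), `respond` (deterministic response
surfaces), and `intersect` (distribution-overlap between two event
files). Note how the analysis itself flags the lowest tuner level: with
almost no sRNA the response barely turns over inside the measured input
range, so its Hill transition point is reported as unidentifiable
rather than as a number.

## Tests

```sh
python -m pytest
```

The suite has 112 unit/property tests across the six modules plus 7
end-to-end scientific acceptance tests (`tests/test_acceptance.py`)
covering: analytic limits of the steady state, stochastic–deterministic
agreement, tuner-response monotonicity, single-cell distinguishability
at low copy number, the overlap statistic's brute-force oracle,
Hill-parameter recovery from synthetic data, and the gating contract.

## Layout

```
src/tunedev/        the package (six modules, see above)
tests/              pytest suite, including tests/test_acceptance.py
scripts/acceptance.py   headline-quantity reproduction script
docs/methods.md     model, algorithms, and numerical choices
```
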