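# File formats

Two dialects carry the same logical schema for sweep sets, selected by
file extension.  All times are ms from sweep start; currents are stored as
recorded (inward negative, pA); field potentials are mV.

## Sweep sets — HDF5 (`.h5`, `.hdf5`)

```
/data            float64, shape (n_sweeps, n_samples)
    @sampling_rate_hz      required scalar
    @stim_time_ms          required scalar
    @holding_potential_mv  optional scalar (absent for field recordings)
    @experiment_id, @cell_id, @animal_id, @genotype, @age_label
                           optional strings
/order_index     int, shape (n_sweeps,)   acquisition order
/timestamp_s     float, shape (n_sweeps,) wall-clock time per sweep
```

## Sweep sets — CSV (`.csv`)

A header block of `# key = value` lines followed by one row per sweep:

```
# sampling_rate_hz = 5000.0
# stim_time_ms = 10.0
# holding_potential_mv = -60.0
# experiment_id = 'expA'
...
sweep_index,order_index,timestamp_s,s0,s1,...,sN
0,0,0.0,-0.031,...
```

`sampling_rate_hz` and `stim_time_ms` are required; a file missing either
is rejected with a format error naming the field.  Floats are written with
`repr` and parsed in round-trip mode, so the array payload survives a
write/read cycle bit-exactly.

## Event tables (`.events.csv`)

One `# experiment_id = ...` line, then a CSV with one row per sweep in
this frozen column order (append-only across versions):

```
sweep_index, order_index, timestamp_s, holding_potential_mv, baseline_pa,
noise_context, peak_pa, peak_latency_ms, amplitude_pa, charge_pc,
is_failure, qc_excluded, qc_reason
```

`amplitude_pa` is the measurement the potency estimators consume: the
template-subtracted peak at −60 mV, the 25-ms read at +40 mV.

## Ground-truth sidecar (`ground_truth.csv`)

Written next to simulated sweep sets: `sweep_index,
holding_potential_mv, quantum_count, is_failure` — the simulator's actual
per-sweep release, for judging the detection stage.
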