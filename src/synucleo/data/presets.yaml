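# Condition presets for the synthetic generators.
#
# sPSC / mPSC event statistics (rate Hz, amplitude pA, whole-recording
# charge nC per 300 s) are the printed per-condition means of the
# experiments the generators emulate; fields left null are not printed for
# that condition and fall back to documented defaults (amplitude -> the
# control value, charge -> a 10 ms decay kernel).
# Kinetic and noise parameters (rise/decay, amplitude CV, noise SD) are
# typical hippocampal PSC values, editable here.

spsc:
  control:            {event_rate_hz: 0.37, mean_amplitude_pa: 359.0, expected_charge_nc: 2.29}
  asyn_0.1uM:         {event_rate_hz: 0.46, mean_amplitude_pa: 454.0, expected_charge_nc: 2.44}
  asyn_0.5uM:         {event_rate_hz: 0.75, mean_amplitude_pa: 701.0, expected_charge_nc: 4.16}
  asyn_1uM:           {event_rate_hz: 1.07, mean_amplitude_pa: 875.0, expected_charge_nc: 5.52}
  gsyn_1uM:           {event_rate_hz: 0.50, mean_amplitude_pa: 488.0, expected_charge_nc: 2.32}
  m30_alone:          {event_rate_hz: 0.14, mean_amplitude_pa: 340.0, expected_charge_nc: 1.87}
  asyn_1uM_fig8:      {event_rate_hz: 1.05, mean_amplitude_pa: 940.0, expected_charge_nc: 6.38}
  asyn_1uM_plus_m30:  {event_rate_hz: 0.23, mean_amplitude_pa: 471.0, expected_charge_nc: 3.23}

mpsc:
  control:            {event_rate_hz: 0.26, mean_amplitude_pa: 49.2, expected_charge_nc: null}
  asyn_0.25uM:        {event_rate_hz: 0.64, mean_amplitude_pa: 49.2, expected_charge_nc: null}
  asyn_0.5uM:         {event_rate_hz: 0.76, mean_amplitude_pa: 63.4, expected_charge_nc: null}
  nonagg_0.5uM:       {event_rate_hz: 0.49, mean_amplitude_pa: 49.2, expected_charge_nc: null}

event_defaults:
  amplitude_cv: 0.4
  rise_ms: 2.0
  decay_ms: 10.0
  noise_sd_pa: 5.0
  sampling_rate_hz: 2000.0
  reference_duration_s: 300.0

tem:
  nonagg: {proportions: [0.93, 0.06, 0.01]}
  asynO:  {proportions: [0.88, 0.11, 0.01]}

# Illustrative Boltzmann parameters for the aggregation time courses
# (percent-of-maximum scale over a 35 h run); the plateau A2 shrinks with
# increasing inhibitor ratio and the non-aggregating homolog stays flat.
tht:
  asyn:          {A1: 0.0, A2: 100.0, x0: 15.0, dx: 2.0}
  asyn_m30_0.5:  {A1: 0.0, A2: 95.0,  x0: 15.5, dx: 2.0}
  asyn_m30_2.5:  {A1: 0.0, A2: 55.0,  x0: 17.0, dx: 2.2}
  asyn_m30_5:    {A1: 0.0, A2: 35.0,  x0: 18.0, dx: 2.5}
  gsyn:          {A1: 0.0, A2: 4.0,   x0: 15.0, dx: 2.0}
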