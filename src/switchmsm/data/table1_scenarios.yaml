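# Null-hypothesis simulation scenario grid: 3000 + 3000 treatment-naive
# initiators per arm, administrative censoring at 8 years, Weibull event
# times (rweibull parameterization), common switching time (years) and
# baseline switching proportion.  Scenarios 1-2 are high-event-count
# illustration scenarios; 3-22 are rare-event scenarios calibrated to a
# common expected event total (~330).
scenarios:
  - {scenario_id: 1, shape: 1.0, scale: 4.0, switch_time: 1.0, switch_prop: 0.30}
  - {scenario_id: 2, shape: 0.3, scale: 2.0, switch_time: 1.0, switch_prop: 0.30}
  - {scenario_id: 3, shape: 1.0, scale: 142.85, switch_time: 1.0, switch_prop: 0.25}
  - {scenario_id: 4, shape: 1.0, scale: 142.85, switch_time: 5.0, switch_prop: 0.25}
  - {scenario_id: 5, shape: 1.0, scale: 142.85, switch_time: 1.0, switch_prop: 0.50}
  - {scenario_id: 6, shape: 1.0, scale: 142.85, switch_time: 5.0, switch_prop: 0.50}
  - {scenario_id: 7, shape: 1.1, scale: 109.93, switch_time: 1.0, switch_prop: 0.25}
  - {scenario_id: 8, shape: 1.1, scale: 109.93, switch_time: 5.0, switch_prop: 0.25}
  - {scenario_id: 9, shape: 1.1, scale: 109.93, switch_time: 1.0, switch_prop: 0.50}
  - {scenario_id: 10, shape: 1.1, scale: 109.93, switch_time: 5.0, switch_prop: 0.50}
  - {scenario_id: 11, shape: 1.2, scale: 88.36, switch_time: 1.0, switch_prop: 0.25}
  - {scenario_id: 12, shape: 1.2, scale: 88.36, switch_time: 5.0, switch_prop: 0.25}
  - {scenario_id: 13, shape: 1.2, scale: 88.36, switch_time: 1.0, switch_prop: 0.50}
  - {scenario_id: 14, shape: 1.2, scale: 88.36, switch_time: 5.0, switch_prop: 0.50}
  - {scenario_id: 15, shape: 1.3, scale: 73.45, switch_time: 1.0, switch_prop: 0.25}
  - {scenario_id: 16, shape: 1.3, scale: 73.45, switch_time: 5.0, switch_prop: 0.25}
  - {scenario_id: 17, shape: 1.3, scale: 73.45, switch_time: 1.0, switch_prop: 0.50}
  - {scenario_id: 18, shape: 1.3, scale: 73.45, switch_time: 5.0, switch_prop: 0.50}
  - {scenario_id: 19, shape: 1.5, scale: 54.66, switch_time: 1.0, switch_prop: 0.25}
  - {scenario_id: 20, shape: 1.5, scale: 54.66, switch_time: 5.0, switch_prop: 0.25}
  - {scenario_id: 21, shape: 1.5, scale: 54.66, switch_time: 1.0, switch_prop: 0.50}
  - {scenario_id: 22, shape: 1.5, scale: 54.66, switch_time: 5.0, switch_prop: 0.50}
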