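# Delayed-flowering (heating) scenario: uncorrected harvest peak one week
# late; the controller applies positive offsets to pull it back to Dec 21.
scenario:
  kind: HT            # CL (cooling), HT (heating), or CT (uncorrected control)
  n_plants: 14
  fruits_per_plant: 7
  seed: 1
  noise_sd_flowering: 0.0    # set both noises to 0 for a perfect-model run
  maturation_noise_sd: 0.0
control:
  target_date: 2019-12-21
  search_min: -5.0
  search_max: 5.0
  search_step: 0.1
  intervention_start: 2019-11-30
  update_dates: [2019-12-04, 2019-12-07, 2019-12-11, 2019-12-14,
                 2019-12-18, 2019-12-21, 2019-12-25, 2019-12-28]
  horizon_end: 2020-01-31
model:
  kind: thermal_threshold
  threshold: 600      # degC*day accumulated from the day after flowering
distribution:
  kernel_sd: 14.34    # days
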