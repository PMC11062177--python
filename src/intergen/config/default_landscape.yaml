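# Default virtual-arrowhead landscape.
# Calibrated with scripts/calibrate_landscape.py so that the win-stay/lose-shift
# ensemble (T=50 trials, L=5, noise sd 5, 10,000 agents) yields optimal
# exploration counts tau* = 12 (unrepaid/asocial) and tau* = 22 (repaid).
# These are calibration values, not the coefficients of the original task.
optimum:
  length: 92
  width: 9
  thickness: 88
weights:
  length: 0.05
  width: 0.05
  thickness: 0.05
peak: 1000
noise_sd: 5
initial_design:
  length: 28
  width: 72
  thickness: 22
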