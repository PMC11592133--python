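# Default metabolite basis and stimulation paradigm for the synthetic generator.
#
# Each metabolite is a list of Lorentzian lines:
#   chemical_shift      ppm
#   relative_amplitude  dimensionless weight within the metabolite
#   t2_star             ms (exponential decay constant of the line)
# Chemical shifts are literature-typical in vivo values at 3 T; relative
# amplitudes are crude proton-weighted stand-ins, not a quantum-mechanical
# basis set.  `concentration` is the default amplitude scale (arbitrary
# units, roughly mM-proportioned) applied by the generator.
basis:
  NAA:
    concentration: 12.0
    peaks:
      - {chemical_shift: 2.008, relative_amplitude: 1.00, t2_star: 90.0}
  tCr:
    concentration: 8.0
    peaks:
      - {chemical_shift: 3.027, relative_amplitude: 1.00, t2_star: 80.0}
      - {chemical_shift: 3.913, relative_amplitude: 0.70, t2_star: 70.0}
  tCho:
    concentration: 2.5
    peaks:
      - {chemical_shift: 3.185, relative_amplitude: 1.00, t2_star: 85.0}
  Glu:
    concentration: 9.0
    peaks:
      - {chemical_shift: 2.350, relative_amplitude: 0.55, t2_star: 60.0}
      - {chemical_shift: 2.080, relative_amplitude: 0.45, t2_star: 60.0}
      - {chemical_shift: 3.750, relative_amplitude: 0.30, t2_star: 70.0}
  Gln:
    concentration: 3.0
    peaks:
      - {chemical_shift: 2.450, relative_amplitude: 0.50, t2_star: 55.0}
      - {chemical_shift: 2.120, relative_amplitude: 0.40, t2_star: 55.0}
      - {chemical_shift: 3.770, relative_amplitude: 0.30, t2_star: 65.0}
  mIns:
    concentration: 5.0
    peaks:
      - {chemical_shift: 3.520, relative_amplitude: 0.80, t2_star: 65.0}
      - {chemical_shift: 3.610, relative_amplitude: 0.60, t2_star: 65.0}
      - {chemical_shift: 4.050, relative_amplitude: 0.30, t2_star: 60.0}

# Capsaicin + heat pain paradigm timing (minutes except tr).
paradigm:
  baseline_duration: 3.12   # resting period before stimulation (Time < 0)
  stimulation_duration: 22.4  # capsaicin on forearm for the whole period
  heat_onset: 9.0           # heat (~41 C) applied this long after stim start
  heat_duration: 4.4
  tr: 4000.0                # ms

# Acquisition noise / instability defaults.
noise:
  # Calibrated once so a single-shot (NSA1) synthetic spectrum scores SNR ~ 5
  # under this package's SNR definition, emulating typical 3T single-average
  # quality for this voxel and sequence.
  noise_sd: 10.0            # complex channel SD per time-domain point
  phase_jitter_sd: 0.05     # rad, zero-order phase per acquisition
  freq_jitter_sd: 1.0       # Hz, global shift per acquisition
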