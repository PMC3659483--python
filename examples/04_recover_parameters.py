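"""Round-trip parameter recovery from a noisy synthetic recording.

Generates a 1 s, 20 kHz spontaneous cSAN recording with +-0.96 mV of
uniform noise, perturbs every model parameter by a random +-20%, and
fits the perturbed model back to the recording with the
curvilinear-gradient optimiser.  Takes a few minutes.
"""

from ionfit import experiments

out = experiments.csan_recovery(seed=11)
print(f"start RMS      : {out['start_rms_mV']:.2f} mV (perturbed model)")
print(f"final RMS      : {out['final_rms_mV']:.2f} mV after {out['iterations']:.0f} iterations")
print(f"noise floor    : {out['noise_floor_mV']:.2f} mV (uniform +-0.96 mV)")
# The fit should land within a few tenths of a millivolt of the noise
# floor — i.e. the waveform is recovered even though individual
# parameters are generally not unique.
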