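# Named geometry presets (micrometres).
# normal / coiled: polymorphic helix forms; wrapped-default: coiled form
# wound around the default capsule body at 0.05 um clearance.
body:
  length_um: 2.5
  radius_um: 0.40
helices:
  normal:   {pitch_um: 2.0, radius_um: 0.3, n_turns: 3.0, handedness: left, taper_fraction: 0.1}
  coiled:   {pitch_um: 1.0, radius_um: 0.5, n_turns: 2.5, handedness: left, taper_fraction: 0.1}
configurations:
  normal:          {mode: unwrapped, helix: normal}
  coiled:          {mode: unwrapped, helix: coiled}
  wrapped-default: {mode: wrapped,  helix: coiled, wrap_clearance_um: 0.05}
filament_radius_um: 0.02
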