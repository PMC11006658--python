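# Baseline head-neck-thorax network: compartments, mean flows, compliances and
# physiological constants for the supine human at rest.  Units: mmHg, mL, min.
constants:
  starling:
    k_cb: 0.066          # blood-brain barrier filtration coefficient, mL/min/mmHg
    sigma_cb: 1.0        # reflection coefficient
    pi_capillary: 21.5   # blood colloid osmotic pressure, mmHg
    pi_brain: 0.0        # brain interstitial osmotic pressure, mmHg
  cranial_compliance:
    c0: 6.5333           # peak craniospinal compliance, mL/mmHg
    r: 0.633431
    gamma: 0.604229
  venous_compliance:
    n_ratio: 0.01        # asymptotic / peak compliance ratio
    alpha_neck: 0.40026          # 1/mmHg
    alpha_central_veins: 0.29352 # 1/mmHg
    peak_transmural: 4.0         # transmural pressure of maximal compliance, mmHg
  cardiac:
    z_heart: 1250.0      # central veins -> heart fluidity, mL/min/mmHg
    s: 1.0               # pumping efficiency
    hr0: 61.6            # baseline heart rate, beats/min
    sv: 77.2             # stroke volume, mL/beat
    alpha_heart: 7.809
    beta: 0.381          # 1/mmHg
    collapse_offset: 2.0 # P_collapse = P_thoracic + 2, mmHg
  baroreflex:
    tau_seconds: 4.0     # heart-rate relaxation time (converted to minutes on load)
    alpha_sigma: 1.15    # sympathetic gain
    beta_sigma: 0.34     # parasympathetic gain
    gamma_sigma: 0.595   # baseline activation
    nu: 7.0              # sigmoid slope
  transmantle_pressure: 0.2   # ventricular minus spinal CSF pressure, mmHg

compartments:
  - {name: Central Arteries,      level: body,     baseline_pressure: 92.0}
  - {name: Intracranial Arteries, level: head,     baseline_pressure: 82.0}
  - {name: Capillaries,           level: head,     baseline_pressure: 34.64}
  - {name: Brain,                 level: head,     baseline_pressure: 11.2}
  - {name: Ventricular CSF,       level: head,     baseline_pressure: 11.2}
  - {name: Cranial CSF,           level: head,     baseline_pressure: 11.1}
  - {name: Venous Sinus,          level: head,     baseline_pressure: 6.6}
  - {name: Jugular,               level: neck,     baseline_pressure: 5.683}
  - {name: Secondary Venous,      level: neck,     baseline_pressure: 5.80}
  - {name: Extrajugular,          level: neck,     baseline_pressure: 5.80}
  - {name: Spinal CSF,            level: body,     baseline_pressure: 11.0}
  - {name: Central Veins,         level: body,     baseline_pressure: 5.0}
  - {name: Thoracic,              level: thoracic, baseline_pressure: -6.0}

# Mean steady-state flows (mL/min).  "literature" rows are primary inputs;
# "conservation" rows are re-derived exactly from volume conservation during
# calibration (the printed value is only validated against the derived one);
# "drainage_fraction" rows share the venous-sinus outflow in the printed
# ratios, with the total fixed by conservation.  The Ventricular CSF - Brain
# edge carries no mean flow and its fluidity is prescribed as 1000 * K_CB.
flows:
  - {source: Central Arteries,      dest: Intracranial Arteries, mean_flow: 795.0,  kind: resistive,       provenance: literature}
  - {source: Central Arteries,      dest: Central Veins,         mean_flow: 4505.0, kind: resistive,       provenance: literature}
  - {source: Intracranial Arteries, dest: Capillaries,           mean_flow: 795.0,  kind: resistive,       provenance: conservation}
  - {source: Capillaries,           dest: Brain,                 mean_flow: 0.13,   kind: starling,        provenance: literature}
  - {source: Capillaries,           dest: Ventricular CSF,       mean_flow: 0.30,   kind: forced_constant, provenance: literature}
  - {source: Capillaries,           dest: Venous Sinus,          mean_flow: 794.57, kind: resistive,       provenance: conservation}
  - {source: Ventricular CSF,       dest: Brain,                 mean_flow: 0.0,    kind: resistive,       provenance: literature, fluidity_kcb_multiple: 1000.0}
  - {source: Ventricular CSF,       dest: Cranial CSF,           mean_flow: 0.30,   kind: resistive,       provenance: conservation}
  - {source: Brain,                 dest: Cranial CSF,           mean_flow: 0.13,   kind: resistive,       provenance: conservation}
  - {source: Cranial CSF,           dest: Venous Sinus,          mean_flow: 0.30,   kind: resistive,       provenance: literature}
  - {source: Cranial CSF,           dest: Spinal CSF,            mean_flow: 0.13,   kind: resistive,       provenance: conservation}
  - {source: Spinal CSF,            dest: Extrajugular,          mean_flow: 0.13,   kind: resistive,       provenance: conservation}
  - {source: Venous Sinus,          dest: Secondary Venous,      mean_flow: 43.72,  kind: resistive,       provenance: drainage_fraction}
  - {source: Venous Sinus,          dest: Extrajugular,          mean_flow: 140.70, kind: resistive,       provenance: drainage_fraction}
  - {source: Venous Sinus,          dest: Jugular,               mean_flow: 610.48, kind: resistive,       provenance: drainage_fraction}
  - {source: Jugular,               dest: Central Veins,         mean_flow: 610.48, kind: resistive,       provenance: conservation}
  - {source: Secondary Venous,      dest: Central Veins,         mean_flow: 43.72,  kind: resistive,       provenance: conservation}
  - {source: Extrajugular,          dest: Central Veins,         mean_flow: 140.70, kind: resistive,       provenance: conservation}

# Compliant interfaces (mL/mmHg).  For "cranial" edges the authoritative
# baseline is the exponential law evaluated at baseline pressures; the printed
# reported_compliance is validated against it at printed precision only.
compliances:
  - {a: Brain,       b: Intracranial Arteries, model: constant, baseline_compliance: 0.021}
  - {a: Brain,       b: Ventricular CSF,       model: cranial,  interface: brain_ventricular_csf,  reported_compliance: 0.054}
  - {a: Brain,       b: Capillaries,           model: constant, baseline_compliance: 0.69}
  - {a: Brain,       b: Venous Sinus,          model: cranial,  interface: brain_venous_sinus,     reported_compliance: 1.33}
  - {a: Cranial CSF, b: Brain,                 model: cranial,  interface: brain_cranial_csf,      reported_compliance: 0.16}
  - {a: Cranial CSF, b: Venous Sinus,          model: cranial,  interface: venous_sinus_cranial_csf, reported_compliance: 0.82}
  - {a: Cranial CSF, b: Secondary Venous,      model: venous,   baseline_compliance: 0.010, transmural: Secondary Venous}
  - {a: Spinal CSF,  b: Central Arteries,      model: constant, baseline_compliance: 0.0057}
  - {a: Jugular,     b: Secondary Venous,      model: venous,   baseline_compliance: 0.40,  transmural: Secondary Venous}
  - {a: Jugular,     b: Jugular,               model: venous,   baseline_compliance: 1.35,  transmural: Jugular}
  - {a: Extrajugular, b: Extrajugular,         model: venous,   baseline_compliance: 16.38, transmural: Extrajugular}
  - {a: Thoracic,    b: Spinal CSF,            model: constant, baseline_compliance: 0.034}
  - {a: Thoracic,    b: Central Veins,         model: venous,   baseline_compliance: 51.86, transmural: Central Veins}
  - {a: Thoracic,    b: Central Arteries,      model: constant, baseline_compliance: 1.62}

# Compartments whose total volume is pinned by the rigid cranium.
monro_kellie:
  - Intracranial Arteries
  - Capillaries
  - Brain
  - Ventricular CSF
  - Cranial CSF
  - Venous Sinus
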