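# Packaged species presets.
#
# populations: hierarchical sampling configs.  mean/sd are collection-level
# spore length/width statistics (µm); concavity_median is the median
# suprahilar-depression fraction of convex-hull area (lognormal across
# spores), set inside the regime each species occupies in the microscopy key
# (pronounced > 3% for C. pulverulentus, shallow < 2.5% for
# C. mediterraneensis, minimal for C. poikilochromus).
#
# shapes: fixed single-silhouette fixtures at the species mean dimensions.
version: 1
populations:
  pulverulentus:
    species_label: "Cyanoboletus pulverulentus"
    mean_L: 12.29
    sd_L_between: 0.90
    mean_W: 4.87
    sd_W_between: 0.32
    within_sd_factor: 1.5
    corr_LW: 0.5
    concavity_median: 0.04
    concavity_log_sd: 0.35
    n_per_basidiome: 5
    m_basidiomes: 10
    p_collections: 15
    profile_family: amygdaliform
    apex_sharpness: 0.7
    apiculus_offset: 0.3
    notch_width_frac: 0.35
  mediterraneensis:
    species_label: "Cyanoboletus mediterraneensis"
    mean_L: 12.67
    sd_L_between: 0.74
    mean_W: 5.33
    sd_W_between: 0.32
    within_sd_factor: 1.5
    corr_LW: 0.5
    concavity_median: 0.015
    concavity_log_sd: 0.35
    n_per_basidiome: 5
    m_basidiomes: 10
    p_collections: 17
    profile_family: subamygdaliform
    apex_sharpness: 0.4
    apiculus_offset: 0.0
    notch_width_frac: 0.35
  poikilochromus:
    species_label: "Cyanoboletus poikilochromus"
    mean_L: 11.83
    sd_L_between: 0.69
    mean_W: 5.03
    sd_W_between: 0.25
    within_sd_factor: 1.5
    corr_LW: 0.5
    concavity_median: 0.010
    concavity_log_sd: 0.35
    n_per_basidiome: 5
    m_basidiomes: 10
    p_collections: 10
    profile_family: ellipsoid
    apex_sharpness: 0.1
    apiculus_offset: 0.0
    notch_width_frac: 0.35
shapes:
  pulverulentus:
    profile_family: amygdaliform
    length_um: 12.29
    width_um: 4.87
    apex_sharpness: 0.7
    apiculus_offset: 0.3
    target_concavity: 0.04
    notch_width_frac: 0.35
  mediterraneensis:
    profile_family: subamygdaliform
    length_um: 12.67
    width_um: 5.33
    apex_sharpness: 0.4
    apiculus_offset: 0.0
    target_concavity: 0.015
    notch_width_frac: 0.35
  poikilochromus:
    profile_family: ellipsoid
    length_um: 11.83
    width_um: 5.03
    apex_sharpness: 0.1
    apiculus_offset: 0.0
    target_concavity: 0.01
    notch_width_frac: 0.35
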