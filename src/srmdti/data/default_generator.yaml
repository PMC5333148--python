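# Default synthetic-cohort conditions: a 42-subject three-group study
# (16 controls, 14 MA, 12 MAP) with a 43-protein serum SRM panel measured
# in duplicate injections, 48-ROI DTI summaries, and psychometrics.
# Demographics copy the recorded cohort exactly (per-group age means/SDs,
# gender and substance counts), so the categorical group tests can be
# regenerated as well as computed from the published counts.
# All planted effect sizes are in residual-SD units; correlations are the
# target Pearson r for the designated scope.

group_sizes: {Control: 16, MA: 14, MAP: 12}
n_proteins: 43
peptides_per_protein: [1, 3]       # inclusive range, drawn per protein
transitions_per_peptide: [2, 3]
replicate_count: 2

base_intensity_log2: [14.0, 22.0]  # uniform range of transition baselines
run_effect_sd: 0.5                 # per-injection systematic shift, log2
transition_noise_sd: 0.3           # per (transition, subject) prep noise, log2
duplicate_cv_target: 0.04          # raw-scale CV between duplicate injections

interference:
  n_transitions: 10                # planted co-eluting transitions
  spike_magnitude: 1.0             # extra log2 spikes in a fraction of runs
  spike_fraction: 0.3

# Group shifts are in residual-SD units.  The recorded cohort's nicotine
# and alcohol counts are heavily confounded with group (every MAP subject
# smokes), which inflates the adjusted contrast SEs by ~1.35x; shifts of
# ~2.5 SD are what the reported adjusted p-values (down to 3e-4 at these
# group sizes) imply after that inflation.
protein_effects:
  - {protein: APOC2, group: MAP, shift: 2.6}
  - {protein: APOH, group: MAP, shift: -2.6, sd_scale: 0.6}
  - {protein: HPTR, group: MAP, shift: 0.8}
  - {protein: HPTR, group: MA, shift: -0.5}

roi_effects:                       # shifts on the eigenvalue (AD/RD) scale;
  - {roi: CST-L, metric: RD, group: MAP, shift: 2.5}   # MD inherits 2/3
  - {roi: CST-R, metric: RD, group: MAP, shift: 2.5}
  - {roi: FXST-L, metric: RD, group: MAP, shift: 2.5}
  - {roi: FXST-R, metric: RD, group: MAP, shift: 2.5}
  - {roi: SCP-L, metric: RD, group: MAP, shift: 2.5}
  - {roi: SCP-R, metric: RD, group: MAP, shift: 2.5}
  - {roi: ICP-L, metric: RD, group: MAP, shift: 2.5}
  - {roi: ICP-R, metric: RD, group: MAP, shift: 2.5}

coupling:                          # latent-factor protein-DTI co-linearity
  - protein: APOH                  # fornix/uncinate coupling, all subjects
    scope: all
    cells:
      - {roi: FX, metric: RD, r: -0.50}
      - {roi: FX, metric: MD, r: -0.53}
      - {roi: UNC-L, metric: MD, r: -0.47}
  - protein: A1AT                  # control-only RD coupling, 15 ROIs
    scope: Control
    r: 0.65
    metric: RD
    rois: [ACR-L, SCR-L, PCR-L, ACR-R, SCR-R, PCR-R, FXST-L, FXST-R,
           ICP-L, ICP-R, FX, SLF-L, SLF-R, EC-L, EC-R]
  - protein: PEDF                  # MAP-only AD coupling
    scope: MAP
    cells:
      - {roi: PCR-L, metric: AD, r: 0.80}
  - proteins: [A2AP, AACT, C1R, CFAB, CO4A, ALBU, APOA1, APOA2, APOA4,
               APOB, APOC1, APOC3]
    scope: Control                 # broad control-only co-linearity block
    r: 0.65
    metric: RD
    rois: [MCP, PCT, GCC, BCC, SCC, CP-L, CP-R, ALIC-L, ALIC-R, PLIC-L,
           PLIC-R, RLIC-L, RLIC-R, PTR-L, PTR-R, SS-L, SS-R, CGC-L, CGC-R,
           UNC-R]
  - proteins: [APOD, APOE, APOM, TTHY, TRFE, CERU, CFAH, CO3, CO5, CO6,
               CO9, CLUS]
    scope: Control
    r: 0.65
    metric: AD
    rois: [MCP, PCT, GCC, BCC, SCC, CP-L, CP-R, ALIC-L, ALIC-R, PLIC-L,
           PLIC-R, RLIC-L, RLIC-R, PTR-L, PTR-R, SS-L, SS-R, CGC-L, CGC-R,
           TAP-L]
  - proteins: [CRP, FIBA, FIBB, FIBG, GELS, HEMO, HPT, IC1, ITIH4, KNG1,
               PLMN, RET4, SAMP, VTDB, APOC2, HPTR]
    scope: Control
    r: 0.65
    metric: AD
    rois: [ACR-L, ACR-R, SCR-L, SCR-R, PCR-R, SLF-L, SLF-R, EC-L, EC-R,
           FXST-L, FXST-R, ICP-L, ICP-R, FX, CGH-L, CGH-R, ML-L, ML-R,
           UNC-R, TAP-R]

roi_baseline:
  ad_mean_range: [1.1e-3, 1.6e-3]  # per-ROI axial diffusivity, mm^2/s
  rd_fraction_range: [0.40, 0.60]  # RD baseline as a fraction of AD
  ad_sd: 5.0e-5                    # between-subject SD, mm^2/s
  rd_sd: 4.0e-5
  global_factor_loading: 0.3       # shared per-subject physiological factor

covariates:                        # per-group [mean, sd] or exact counts
  age: {Control: [25.56, 5.99], MA: [22.71, 3.07], MAP: [25.0, 7.39]}
  education_years: {Control: [12.13, 1.41], MA: [10.29, 1.98], MAP: [9.75, 1.22]}
  gender_male: {Control: 14, MA: 10, MAP: 9}
  nicotine: {Control: 7, MA: 9, MAP: 12}
  cannabis: {Control: 5, MA: 2, MAP: 1}
  alcohol: {Control: 6, MA: 7, MAP: 1}
  mandrax: {Control: 0, MA: 0, MAP: 1}
  meth_duration_years: {MA: [5.64, 2.31], MAP: [6.46, 2.92]}

psychometrics:
  epqrs_psychoticism: {Control: [2.56, 1.55], MA: [2.29, 1.86], MAP: [2.83, 1.95]}
  epqrs_extraversion: {Control: [9.94, 2.38], MA: [9.14, 2.25], MAP: [7.17, 2.55]}
  epqrs_neuroticism: {Control: [2.63, 2.36], MA: [4.86, 2.88], MAP: [5.00, 2.92]}
  epqrs_total: {Control: [20.38, 5.08], MA: [19.93, 4.57], MAP: [20.58, 3.92]}
  panss_positive: {MAP: [12.5, 5.66]}
  panss_negative: {MAP: [15.5, 10.05]}
  panss_total: {MAP: [50.58, 23.71]}

seed: 0
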