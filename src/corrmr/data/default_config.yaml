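# Default analysis configuration: the coffee-consumption MR study layout.
# Null paths mean "use the packaged fixture" for exposure/LD/annotations and
# "no data available" for outcomes (consortium summary statistics are not
# redistributable; point `path` at local TSVs to run the estimation).
exposure:
  path: null
  trait_name: habitual coffee consumption (cups/day)
ld:
  path: null
annotations:
  path: null
alpha: 0.05
n_tests: 18
subsets: [all, no_known_pleiotropy, functional]
selection:
  # The packaged instrument table is the discovery GWAS's certified
  # genome-wide significant list (Bayesian criterion), so no p re-filter.
  p_threshold: 1.0
  r2_prune: 0.8
  proxy_r2_min: 0.65
  proxy_freq_tol: 0.08
outcomes:
  - name: Type 2 diabetes mellitus
    trait_type: binary
    studies:
      - {consortium: DIAGRAM, path: null}
  - name: Ischemic heart disease
    trait_type: binary
    studies:
      - {consortium: CARDIoGRAMplusC4D 1000 Genomes-based GWAS, path: null}
      - {consortium: CARDIoGRAMplusC4D Metabochip/CARDIoGRAM, path: null}
    overlap:
      n_cases_1: 60801
      n_controls_1: 123504
      n_cases_2: 63746
      n_controls_2: 130681
      shared_cases: 34961      # 57.5% of the smaller study's cases
      shared_controls: 49525   # 40.1% of the first-listed study's controls
  - name: Depression
    trait_type: binary
    studies:
      - {consortium: PGC, path: null}
  - name: Alzheimer's disease
    trait_type: binary
    studies:
      - {consortium: IGAP, path: null}
  - name: HDL-cholesterol (SD)
    trait_type: continuous
    studies:
      - {consortium: GLGC, path: null}
  - name: LDL-cholesterol (SD)
    trait_type: continuous
    studies:
      - {consortium: GLGC, path: null}
  - name: Triglycerides (SD)
    trait_type: continuous
    studies:
      - {consortium: GLGC, path: null}
  - name: Body mass index (SD)
    trait_type: continuous
    studies:
      - {consortium: GIANT, path: null}
  - name: Waist-hip ratio (SD)
    trait_type: continuous
    studies:
      - {consortium: GIANT, path: null}
  - name: HbA1c (%)
    trait_type: continuous
    studies:
      - {consortium: MAGIC, path: null}
  - name: Fasting glucose (mmol/L)
    trait_type: continuous
    studies:
      - {consortium: MAGIC, path: null}
  - name: Fasting insulin (log-transformed)
    trait_type: continuous
    studies:
      - {consortium: MAGIC, path: null}
  - name: Fasting glucose (mmol/L, 2010 release)
    trait_type: continuous
    studies:
      - {consortium: MAGIC, path: null}
  - name: Fasting insulin (log-transformed, 2010 release)
    trait_type: continuous
    studies:
      - {consortium: MAGIC, path: null}
  - name: Beta-cell function (HOMA-B, log-transformed)
    trait_type: continuous
    studies:
      - {consortium: MAGIC, path: null}
  - name: Insulin resistance (HOMA-IR, log-transformed)
    trait_type: continuous
    studies:
      - {consortium: MAGIC, path: null}
  - name: Adiponectin (log-transformed)
    trait_type: continuous
    studies:
      - {consortium: ADIPOGen, path: null}
  - name: Childhood cognition
    trait_type: continuous
    studies:
      - {consortium: SSGAC, path: null}
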