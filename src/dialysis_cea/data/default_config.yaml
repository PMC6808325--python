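# Default model inputs: MOH-perspective annual costs (RM, 2017), EQ-5D-3L
# utilities, and MDTR annual transition rates for the HD-vs-CAPD cost-utility
# model.  Ranges are the published plausible ranges used for one-way and
# probabilistic sensitivity analysis.
currency: RM (2017)
costs:
  HD:
    components:
      outpatient:           {mean: 5316.41,  low: 1993.95,  high: 11399.97}
      access_surgeries:     {mean: 1209.24,  low: 337.07,   high: 4865.86}
      building_land:        {mean: 783.95,   low: 162.94,   high: 2214.31}
      equipment:            {mean: 3299.05,  low: 2591.24,  high: 4424.78}
      staff:                {mean: 14818.36, low: 11420.38, high: 17499.80}
      overheads:            {mean: 1775.30,  low: 568.67,   high: 2914.41}
      dialysis_consumables: {mean: 11700.99, low: 10803.51, high: 12530.71}
      hospitalization:      {mean: 887.28,   low: 0.00,     high: 18171.19}
    total:                  {mean: 39790.58, low: 30663.33, high: 55996.57}
  CAPD:
    components:
      outpatient:           {mean: 4482.61,  low: 1842.79,  high: 12401.07}
      access_surgeries:     {mean: 477.26,   low: 199.80,   high: 1257.33}
      building_land:        {mean: 68.57,    low: 30.44,    high: 111.90}
      equipment:            {mean: 417.73,   low: 146.20,   high: 888.35}
      staff:                {mean: 3815.55,  low: 3011.47,  high: 4761.59}
      overheads:            {mean: 223.72,   low: 90.12,    high: 540.42}
      dialysis_consumables: {mean: 26486.05, low: 25826.99, high: 27171.01}
      hospitalization:      {mean: 1604.55,  low: 0.00,     high: 17838.78}
    total:                  {mean: 37576.03, low: 31867.17, high: 55817.90}
utilities:
  HD:   {mean: 0.854, low: 0.290, high: 1.000}
  CAPD: {mean: 0.905, low: 0.564, high: 1.000}
# Annual event rates (events per patient-year); converted to per-cycle
# probabilities with p = 1 - exp(-r t) when the transition matrix is built.
transition_rates:
  CAPD_HD:    {mean: 0.067, low: 0.058, high: 0.081}
  CAPD_death: {mean: 0.134, low: 0.105, high: 0.151}
  HD_CAPD:    {mean: 0.007, low: 0.002, high: 0.011}
  HD_death:   {mean: 0.125, low: 0.119, high: 0.136}
# Initial modality mix (HD:CAPD) per provision strategy.
scenarios:
  base_case: {init_HD: 0.60, init_CAPD: 0.40}
  scenario1: {init_HD: 0.55, init_CAPD: 0.45}
  scenario2: {init_HD: 0.50, init_CAPD: 0.50}
  scenario3: {init_HD: 0.70, init_CAPD: 0.30}
economics:
  discount_rate: 0.03
  n_cycles: 5
  cycle_length: 1.0
  wtp_thresholds:
    very_cost_effective: 40000.0   # ~1x GDP per capita (RM)
    cost_effective: 120000.0       # ~3x GDP per capita (RM)
  life_years:
    HD: 4.15
    CAPD: 3.70
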