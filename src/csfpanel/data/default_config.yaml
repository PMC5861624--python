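# Default analysis + cohort-design configuration.
#
# Per-group biomarker entries are median / Q1 / Q3 (assay units) and the
# number of subjects with a measurement; demographics are median / Q1 / Q3.
# Between-biomarker log-scale correlations are an assumption (no published
# correlation structure exists for these cohorts): a common value within the
# amyloid-processing family, a higher one for the T-tau/P-tau pair, and a
# weak positive default elsewhere.

analysis:
  target_sensitivity: 0.85
  ci_level: 0.95
  pairwise_alpha: 0.05
  bonferroni_threshold: 0.003
  bootstrap_replications: 2000
  joint_min_group_size: 10   # strict: both groups must exceed this
  seed: 20180320

biomarkers:
  abeta_1_42: {units: pg/mL, direction: lower}
  t_tau:      {units: pg/mL, direction: higher}
  p_tau_181:  {units: pg/L,  direction: higher}
  nfl:        {units: ng/L,  direction: lower}
  ykl_40:     {units: ng/mL, direction: higher}
  abx_38:     {units: ng/L,  direction: lower}
  abx_40:     {units: ng/L,  direction: lower}
  abx_42:     {units: ng/L,  direction: lower}
  sappa:      {units: ng/mL, direction: higher}
  sappb:      {units: ng/mL, direction: higher}

ratios:
  t_tau_abeta_1_42: {numerator: t_tau,  denominator: abeta_1_42, direction: higher}
  abx42_abx40:      {numerator: abx_42, denominator: abx_40,     direction: lower}

correlation:
  amyloid_family: 0.5     # abeta_1_42, abx_38, abx_40, abx_42, sappa, sappb
  tau_pair: 0.7           # t_tau with p_tau_181
  default: 0.3

detection_limits:
  lower_factor: 0.1       # times the pooled median
  upper_factor: 10.0

cohorts:
  test:
    groups: {AD: 156, DLB: 20, bvFTD: 45, PNFA: 17, SD: 7, HC: 30}
    confirmed: {AD: 13, DLB: 1, bvFTD: 9, PNFA: 2, SD: 1}
    demographics:
      AD:    {age: [62.5, 57, 68], pct_male: 42.3, onset: [36, 24, 60],   onset_n: 154, mmse: [22, 17, 25],   mmse_n: 142}
      DLB:   {age: [70.0, 68, 75], pct_male: 75.0, onset: [36, 18.5, 48], mmse: [22, 18, 28],   mmse_n: 15}
      bvFTD: {age: [61.0, 57, 66], pct_male: 60.0, onset: [36, 24, 60],   onset_n: 44,  mmse: [24, 18, 27],   mmse_n: 42}
      PNFA:  {age: [65.0, 61, 69], pct_male: 47.1, onset: [36, 24, 48],   mmse: [25, 9.5, 28],  mmse_n: 8}
      SD:    {age: [62.0, 57, 68], pct_male: 71.4, onset: [60, 18, 72],   mmse: [27, 16, 27],   mmse_n: 7}
      HC:    {age: [63.5, 50, 67], pct_male: 46.7, mmse: [30, 30, 30]}
    biomarkers:
      AD:
        abeta_1_42: {median: 310.5,  q1: 218.0,  q3: 451.5}
        t_tau:      {median: 674.5,  q1: 430.0,  q3: 973.5}
        p_tau_181:  {median: 86.4,   q1: 59.4,   q3: 111.8,  n: 119}
        nfl:        {median: 1191.5, q1: 857.6,  q3: 1584.0, n: 119}
        ykl_40:     {median: 163,    q1: 127,    q3: 194,    n: 114}
        abx_38:     {median: 1462.0, q1: 1101.4, q3: 2025.5, n: 117}
        abx_40:     {median: 3635.1, q1: 2911.0, q3: 4584.4, n: 117}
        abx_42:     {median: 164.6,  q1: 109.1,  q3: 231.6,  n: 117}
        sappa:      {median: 348.8,  q1: 254.9,  q3: 532.7,  n: 119}
        sappb:      {median: 202.2,  q1: 151.2,  q3: 325.8,  n: 119}
      DLB:
        abeta_1_42: {median: 357.5,  q1: 327.0,  q3: 490.0}
        t_tau:      {median: 338.5,  q1: 185.0,  q3: 489.0}
        p_tau_181:  {median: 47.1,   q1: 38.1,   q3: 64.3,   n: 16}
        nfl:        {median: 929.6,  q1: 839.9,  q3: 1650.1, n: 17}
        ykl_40:     {median: 158,    q1: 134,    q3: 186,    n: 16}
        abx_38:     {median: 1214.2, q1: 840.1,  q3: 1529.2, n: 15}
        abx_40:     {median: 2916.1, q1: 2235.6, q3: 3718.2, n: 15}
        abx_42:     {median: 182.1,  q1: 170.9,  q3: 281.7,  n: 15}
        sappa:      {median: 218.6,  q1: 175.8,  q3: 368.1,  n: 16}
        sappb:      {median: 138.0,  q1: 115.0,  q3: 175.2,  n: 16}
      bvFTD:
        abeta_1_42: {median: 638.0,  q1: 396.0,  q3: 871.0}
        t_tau:      {median: 289.0,  q1: 187.0,  q3: 389.0}
        p_tau_181:  {median: 49.2,   q1: 37.0,   q3: 64.0,   n: 39}
        nfl:        {median: 1788.4, q1: 839.9,  q3: 3334.6, n: 38}
        ykl_40:     {median: 163,    q1: 135,    q3: 244,    n: 35}
        abx_38:     {median: 1306.0, q1: 1106.2, q3: 1658.8, n: 34}
        abx_40:     {median: 3439.5, q1: 2714.7, q3: 4274.9, n: 34}
        abx_42:     {median: 284.5,  q1: 195.2,  q3: 369.4,  n: 34}
        sappa:      {median: 270.7,  q1: 164.9,  q3: 328.7,  n: 37}
        sappb:      {median: 128.0,  q1: 107.4,  q3: 187.1,  n: 37}
      PNFA:
        abeta_1_42: {median: 440.0,  q1: 308.0,  q3: 696.0}
        t_tau:      {median: 501.0,  q1: 367.0,  q3: 744.0}
        p_tau_181:  {median: 62.5,   q1: 49.8,   q3: 100.1,  n: 13}
        nfl:        {median: 1974.9, q1: 1627.7, q3: 3490.5, n: 12}
        ykl_40:     {median: 192,    q1: 140,    q3: 207,    n: 10}
        abx_38:     {median: 1653.8, q1: 1251.7, q3: 2046.7, n: 12}
        abx_40:     {median: 3900.6, q1: 3175.7, q3: 4355.6, n: 12}
        abx_42:     {median: 183.0,  q1: 117.4,  q3: 343.6,  n: 12}
        sappa:      {median: 374.3,  q1: 316.1,  q3: 467.3,  n: 12}
        sappb:      {median: 220.3,  q1: 178.8,  q3: 298.1,  n: 12}
      SD:
        abeta_1_42: {median: 767.0,  q1: 633.0,  q3: 859.0}
        t_tau:      {median: 319.0,  q1: 229.0,  q3: 458.0}
        p_tau_181:  {median: 50.9,   q1: 25.5,   q3: 58.6}
        nfl:        {median: 2400.0, q1: 1687.5, q3: 3584.7, n: 6}
        ykl_40:     {median: 179,    q1: 132,    q3: 256,    n: 5}
        abx_38:     {median: 1751.4, q1: 1442.0, q3: 1777.0, n: 5}
        abx_40:     {median: 3965.4, q1: 3702.2, q3: 4537.6, n: 5}
        abx_42:     {median: 346.0,  q1: 309.9,  q3: 372.1,  n: 5}
        sappa:      {median: 379.5,  q1: 281.7,  q3: 479.8,  n: 5}
        sappb:      {median: 181.9,  q1: 171.4,  q3: 236.4,  n: 5}
      HC:
        abeta_1_42: {median: 953.0,  q1: 771.0,  q3: 1199.0}
        t_tau:      {median: 303.5,  q1: 189.0,  q3: 402.0}
        p_tau_181:  {median: 47.8,   q1: 39.3,   q3: 65.4,   n: 26}
        nfl:        {median: 649.0,  q1: 515.9,  q3: 849.5}
        ykl_40:     {median: 111,    q1: 93,     q3: 164,    n: 29}
        abx_38:     {median: 2183,   q1: 1980.8, q3: 3058.6, n: 29}
        abx_40:     {median: 5478.3, q1: 4888.3, q3: 7615.2, n: 29}
        abx_42:     {median: 592.2,  q1: 469.7,  q3: 749.8,  n: 29}
        sappa:      {median: 426.4,  q1: 322.0,  q3: 654.5}
        sappb:      {median: 258.6,  q1: 182.0,  q3: 372.0}
  validation:
    groups: {AD: 104, DLB: 5, bvFTD: 12, PNFA: 3, SD: 9, HC: 10}
    confirmed: {}
    # No published per-group summaries exist for this cohort; group
    # distributions are inherited from the test-cohort specs above.
    distributions_from: test
    # Only five measures were available in this cohort; the ratio columns
    # are derived from the two base amyloid peptides.
    measured: [abeta_1_42, t_tau, p_tau_181, abx_40, abx_42]
    # Whole-cohort availability: p_tau 131/143, amyloid peptides 140/143.
    availability_fraction:
      abeta_1_42: 1.0
      t_tau: 1.0
      p_tau_181: 0.9161
      abx_40: 0.979
      abx_42: 0.979
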