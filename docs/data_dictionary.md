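# Data dictionary

## `cohort.csv` — one row per simulated subject

| column | units | description |
|---|---|---|
| `subject` | — | subject index within the run |
| `delayed_missing` | bool | delayed (90 min) scan not acquired; WOR and all `delayed_*` columns are empty |
| `early_suv_max` / `delayed_suv_max` | g/mL | maximum SUV in the tumor VOI |
| `early_suv_mean` / `delayed_suv_mean` | g/mL | mean SUV in the tumor VOI |
| `early_suv_sd` / `delayed_suv_sd` | g/mL | population SD of SUV over the tumor VOI |
| `early_ftv_mL` / `delayed_ftv_mL` | mL | functional tumor volume of the 42% iso-contour VOI |
| `early_tlmu` / `delayed_tlmu` | g | total lesion mitochondrial uptake, FTV × SUV_mean |
| `early_tbr_max` / `delayed_tbr_max` | — | SUV_max,tumor / SUV_mean,background |
| `early_tbr_mean` / `delayed_tbr_mean` | — | SUV_mean,tumor / SUV_mean,background |
| `early_cov_pct` / `delayed_cov_pct` | % | 100 × SD / SUV_mean over the tumor VOI |
| `wor_pct` | % | wash-out rate, 100 × (TBR_early − TBR_late)/TBR_early |
| `wor_basis` | — | which TBR variant fed the WOR formula (`mean` or `max`) |
| `mbi_ftv_mL` | mL | planar ellipsoid volume π/6 · a · b · c from measured diameters |
| `mbi_diam_a_mm`, `mbi_diam_b_mm`, `mbi_diam_c_mm` | mm | measured perpendicular lesion diameters (a: left-right, b: anterior-posterior, c: cranio-caudal) |
| `mbi_mean_counts` | counts | tumor-ROI counts averaged over the CC/MLO/LAT views |
| `mbi_tbr_max` | — | overall max tumor pixel / highest per-view background mean |
| `mbi_tbr_ave` | — | mean of per-view tumor maxima / pooled background mean |
| `mbi_cov_max_pct` | % | 100 × highest per-view SD / highest per-view mean |
| `mbi_cov_ave_pct` | % | 100 × average per-view SD / average per-view mean |
| `mbi_cov_norm` | counts | average per-view SD / (pooled tumor mean / pooled background mean) |
| `mbi_ftv_excluded` | bool | manual field-of-view/diffuse-growth exclusion flag (not inferred) |
| `ftv_true_mL` | mL | generating ellipsoid tumor volume (ground truth) |
| `tbr_true` | — | generating tumor-to-background activity ratio |
| `cov_true` | % | generating voxel-level tumor heterogeneity |
| `wor_true_pct` | % | generating wash-out, 100 × washout_fraction |

## `comparisons.csv` / `comparisons.json` — one row per comparison

| column | description |
|---|---|
| `name` | comparison label (e.g. `ftv_spect_vs_mbi`) |
| `test` | test actually run: `paired-t`, `wilcoxon`, `independent-t`, `mann-whitney`, `levene` |
| `statistic`, `p_value` | test statistic and two-sided p-value |
| `x`, `y` | per-arm summary, `mean (SD)` if normal else `median (IQR)` |
| `spearman_rho`, `spearman_p` | Spearman rank correlation of the retained pairs |
| `n` | complete pairs (or smaller arm) used |
| `notes` | qualifiers (e.g. spread comparison) |

## `provenance.json`

Configuration dictionary, master seed, package name and version of the run
that produced the directory.

## `truth.json` (from `mibiquant simulate`)

`PhantomTruth` fields: `ftv_true_mL`, `tbr_true`, `cov_true`,
`wor_true_pct`, activity scalars, tumor and mirrored background centres.
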