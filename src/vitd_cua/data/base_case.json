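{
  "_comment": [
    "Published base-case inputs for the vitamin D / pediatric ARI cost-utility model.",
    "parameters: point values. distributions: family + center (mean; median for",
    "lognormal) + spread (SD; log-scale SD for lognormal). settings: horizon and",
    "willingness-to-pay. Costs are 2020 USD; probabilities apply over the 182-day",
    "(six-month) horizon; no discounting."
  ],
  "parameters": {
    "p_ari": 0.22,
    "rr_vitd": 0.71,
    "m_ari": 0.0001,
    "m_all": 0.0008,
    "du_ari": 0.06,
    "c_ari_day": 880.0,
    "c_vitd_day": 0.08
  },
  "distributions": {
    "p_ari": {"family": "beta", "center": 0.22, "spread": 0.005},
    "rr_vitd": {"family": "lognormal", "center": 0.71, "spread": 0.11},
    "m_ari": {"family": "beta", "center": 0.0001, "spread": 0.000029},
    "m_all": {"family": "beta", "center": 0.0008, "spread": 0.00022},
    "du_ari": {"family": "beta", "center": 0.06, "spread": 0.015},
    "c_ari_day": {"family": "gamma", "center": 880.0, "spread": 222.0},
    "c_vitd_day": {"family": "gamma", "center": 0.08, "spread": 0.02}
  },
  "settings": {
    "episode_days": 10.0,
    "suppl_days": 182.0,
    "horizon_days": 182.0,
    "wtp": 19000.0,
    "scale_by_horizon": false
  }
}
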