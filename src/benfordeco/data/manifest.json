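{
 "fixtures": {
  "succession_early": {
   "tally_file": "succession_early.csv",
   "tally_sha256": "9795d22d5e535a2e7dadc3117056487b134dc67396c9eb00a564bca5df3df869",
   "source_table": "Table 2 (early succession)",
   "case_label": "1A",
   "expected": {
    "n": 159,
    "morrow_d": 0.782,
    "ssd": 38.4,
    "cohen_w": 0.184,
    "max_pr": 1.38,
    "kl_d": 0.0071,
    "om": 6,
    "ci_w": [
     0.181,
     0.186
    ],
    "ci_ssd": [
     37.9,
     38.9
    ]
   }
  },
  "succession_late": {
   "tally_file": "succession_late.csv",
   "tally_sha256": "41363021fd3ccc0acf1140effbe8c1649c18896bf39c1540e48c77a74e05d807",
   "source_table": "Table 2 (late succession)",
   "case_label": "1B",
   "expected": {
    "n": 208,
    "morrow_d": 0.664,
    "ssd": 21.2,
    "cohen_w": 0.171,
    "max_pr": 1.59,
    "kl_d": 0.0068,
    "om": 6,
    "ci_w": [
     0.168,
     0.175
    ],
    "ci_ssd": [
     18.7,
     23.7
    ]
   }
  },
  "diatoms_small": {
   "tally_file": "diatoms_small.csv",
   "tally_sha256": "eefa27848a5ebd39ebddd6d761fda93a4b76f7749aabdef1b9b3f4995923f8c4",
   "source_table": "Table 3 (small islands)",
   "case_label": "2A",
   "expected": {
    "n": 105,
    "morrow_d": 0.759,
    "ssd": 54.9,
    "cohen_w": 0.25,
    "max_pr": 1.87,
    "kl_d": 0.0125,
    "kl_d_tol": 0.0001,
    "om": 6,
    "ci_w": [
     0.242,
     0.257
    ],
    "ci_ssd": [
     48.1,
     61.7
    ]
   }
  },
  "diatoms_large": {
   "tally_file": "diatoms_large.csv",
   "tally_sha256": "53a0d4b9144725b1987283e88d25bdb2c2963c84c0818cfb093998c3af1f2d62",
   "source_table": "Table 3 (large islands)",
   "case_label": "2B",
   "expected": {
    "n": 148,
    "morrow_d": 1.147,
    "ssd": 88.9,
    "cohen_w": 0.316,
    "max_pr": 1.98,
    "kl_d": 0.0238,
    "ssd_tol": 0.06,
    "om": 6,
    "ci_w": [
     0.308,
     0.323
    ],
    "ci_ssd": [
     79.7,
     98.2
    ]
   }
  },
  "salamanders_pre1990": {
   "tally_file": "salamanders_pre1990.csv",
   "tally_sha256": "595dc610927c987aeda693b4e4621d34a10fe977c4be437dcf64c558a5ea0c9b",
   "source_table": "Table 4 (pre-1990)",
   "case_label": "3A",
   "expected": {
    "n": 96,
    "morrow_d": 0.783,
    "ssd": 63.9,
    "cohen_w": 0.195,
    "max_pr": 1.13,
    "kl_d": 0.0083,
    "om": 2,
    "ci_w": [
     0.193,
     0.197
    ],
    "ci_ssd": [
     62.8,
     65.0
    ]
   }
  },
  "salamanders_post1990": {
   "tally_file": "salamanders_post1990.csv",
   "tally_sha256": "f4ab3f705ceb56ec142f4c602a139d541e73a58e1ba027019abd5615139d99fc",
   "source_table": "Table 4 (post-1990)",
   "case_label": "3B",
   "expected": {
    "n": 173,
    "morrow_d": 1.437,
    "ssd": 119.4,
    "cohen_w": 0.328,
    "max_pr": 2.23,
    "kl_d": 0.026,
    "om": 3,
    "ci_w": [
     0.323,
     0.332
    ],
    "ci_ssd": [
     105.7,
     133.1
    ]
   }
  },
  "fish_ewh": {
   "tally_file": "fish_ewh.csv",
   "tally_sha256": "1db7a0ec9c83d5c737b350592084ffa6d6ed47244bb0e716cf6bf749ba1419c2",
   "source_table": "Table 6",
   "case_label": "4",
   "expected": {
    "n": 141,
    "morrow_d": 0.638,
    "ssd": 28.9,
    "cohen_w": 0.182,
    "max_pr": 1.46,
    "kl_d": 0.0083,
    "om": 4,
    "ci_w": [
     0.177,
     0.187
    ],
    "ci_ssd": [
     26.4,
     31.4
    ],
    "digit_means": [
     5.58,
     3.28,
     8.73,
     7.68,
     7.66,
     13.28,
     17.93,
     20.46,
     3.4
    ],
    "digit_variances": [
     298,
     43,
     208,
     274,
     270,
     658,
     1213,
     1619,
     20
    ],
    "taylor_a": 3.36,
    "taylor_b": 2.07
   },
   "raw_file": "fish_ewh_raw.csv",
   "raw_sha256": "1ae5a3a0d31b4b7b058fc28b983fefd7fbd3850c774a7eda556ad5e6156fa75c"
  },
  "combined_steady_state": {
   "tally_file": "combined_steady_state.csv",
   "tally_sha256": "5d2b43cbdbaa712e7a06ce8c4e1bed944ba94c876ef7d6ffa47097898261d51c",
   "source_table": "Table 8",
   "case_label": "1A+1B+3A+4",
   "expected": {
    "n": 604,
    "morrow_d": 0.632,
    "ssd": 6.62,
    "cohen_w": 0.091,
    "max_pr": 1.28,
    "kl_d": 0.0019,
    "ci_w": [
     0.088,
     0.093
    ],
    "ci_ssd": [
     6.56,
     6.68
    ]
   }
  }
 }
}
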