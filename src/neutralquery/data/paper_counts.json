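{
  "version": 1,
  "experiments": {
    "exp1": {"knowledgeable": [14, 22], "ignorant": [7, 22], "age_range_months": [51, 70]},
    "exp2": {"knowledgeable": [12, 18], "ignorant": [6, 18], "age_range_months": [48, 72]},
    "exp3": {"knowledgeable": [22, 36], "ignorant": [13, 36], "age_range_months": [48, 80]},
    "exp4": {"knowledgeable": [14, 36], "ignorant": [5, 36], "age_range_months": [48, 71]}
  },
  "pooled": {
    "all": {"knowledgeable": [62, 112], "ignorant": [31, 112]},
    "exp123": {"knowledgeable": [48, 76], "ignorant": [26, 76]}
  },
  "age_split": {
    "overall": {"older": [55, 112], "younger": [38, 112]},
    "knowledgeable": {"older": [36, 56], "younger": [26, 56]},
    "ignorant": {"older": [18, 56], "younger": [13, 56]}
  },
  "childes": {
    "n_answered": 732,
    "n_followed_up": 226,
    "followups": {"positive": 144, "negative": 26, "neutral": 56},
    "verifiable": {
      "n": 84,
      "correct": {"positive": 59, "negative": 0, "neutral": 5},
      "incorrect": {"positive": 0, "negative": 13, "neutral": 7}
    }
  }
}
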