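{
 "rng_seed": 42,
 "n_bins": 8,
 "features": {
  "SUVmax": 9.780601164730804,
  "SUVmin": 1.0662604277590497,
  "SUVmean": 5.436734698314799,
  "SUVdiff": 8.714340736971755,
  "MTV": 8.427392875000002,
  "Variance": 6.046265604914339,
  "STD": 2.458915534318806,
  "Skewness": -0.05845053870373092,
  "Kurtosis": 1.8203668649472156,
  "Entropy.image": 2.9459434638613744,
  "Energy": 0.13407999999999998,
  "Contrast": 9.31485576923077,
  "Dissimilarity": 2.489375,
  "Homogeneity.1": 0.39504017857142854,
  "Homogeneity.2": 0.30655341095097877,
  "Correlation": -0.01857777239474383,
  "Difference Entropy.1": 2.6948590468419136,
  "Joint Entropy.2": 5.608456668129462,
  "Sum Entropy.3": 3.510926200319753,
  "Short.Run.Emphasis": 0.9395706303942042,
  "Long.Run.Emphasis": 1.2734486869530284,
  "Gray.Level.Non-Uniformity": 15.31838389472853,
  "Gray.Level.Non-Uniformity.Normalized": 0.13300563674321073,
  "Run.Length.Non-Uniformity": 98.46486545281056,
  "Run.Length.Non-Uniformity.Normalized": 0.8540980713945303,
  "Run.Percentage": 0.9212307692307693,
  "GrayLevelVariance": 6.310376492194678,
  "SmallAreaHighGrayLevelEmphasis": 12.305606079693383,
  "GrayLevelNonUniformity": 4.454545454545454,
  "GrayLevelNonUniformityNormalized": 0.13498622589531678,
  "SizeZoneNonUniformity": 5.909090909090909,
  "SizeZoneNonUniformityNormalized": 0.1790633608815427,
  "LargeAreaEmphasis": 29.363636363636363,
  "ZoneVariance": 15.01561065197428,
  "ZonePercentage": 0.264
 }
}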