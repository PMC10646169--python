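# published posterior summaries of BCR-level annual trend slopes (log scale)
# pr_pct = posterior probability (%) of a >=1% annual change in the direction of the mean
species,bcr,mean,lcri,ucri,pr_pct
Bewick's Wren,9,0.154,-0.108,0.486,82.5
Bewick's Wren,10,0.048,-0.031,0.127,84.3
Bewick's Wren,15,0.322,-0.015,0.765,96.8
Bewick's Wren,16,0.083,0.021,0.146,99.2
Bewick's Wren,18,0.242,0.054,0.429,99.3
Bewick's Wren,33,0.027,-0.353,0.355,56.9
Bewick's Wren,34,0.098,-0.347,0.537,65.6
Black-throated Gray Warbler,9,0.045,-0.073,0.177,70.8
Black-throated Gray Warbler,10,0.029,-0.052,0.113,66.1
Black-throated Gray Warbler,16,-0.027,-0.059,0.004,85.8
Black-throated Gray Warbler,33,0.059,-0.21,0.369,62.8
Black-throated Gray Warbler,34,0.008,-0.317,0.339,49.7
Brewer's Sparrow,9,0.042,-0.022,0.107,83.4
Brewer's Sparrow,10,0.107,0.084,0.13,100.0
Brewer's Sparrow,11,-0.079,-0.168,0.001,95.2
Brewer's Sparrow,15,0.059,-0.211,0.331,64.3
Brewer's Sparrow,16,0.006,-0.033,0.045,44.3
Brewer's Sparrow,17,0.017,-0.027,0.059,63.1
Brewer's Sparrow,18,-0.003,-0.071,0.066,42.1
Brewer's Sparrow,33,-0.1,-0.364,0.159,76.0
Gray Flycatcher,9,0.037,-0.094,0.165,65.7
Gray Flycatcher,10,0.112,0.038,0.188,99.6
Gray Flycatcher,16,-0.049,-0.093,-0.001,94.5
Gray Flycatcher,17,0.137,-0.091,0.387,85.7
Gray Flycatcher,18,-0.632,-1.61,-0.058,98.5
Gray Flycatcher,33,0.028,-0.229,0.323,53.1
Gray Flycatcher,34,0.051,-0.292,0.362,60.3
Gray Vireo,9,0.173,-0.044,0.403,93.8
Gray Vireo,10,0.295,0.069,0.54,99.4
Gray Vireo,16,0.051,-0.002,0.108,93.3
Gray Vireo,18,-0.533,-1.486,0.071,94.8
Gray Vireo,33,0.137,-0.17,0.44,81.3
Gray Vireo,34,-0.491,-1.408,0.129,92.1
Green-tailed Towhee,9,-0.083,-0.208,0.036,88.7
Green-tailed Towhee,10,0.084,0.055,0.115,100.0
Green-tailed Towhee,15,-0.003,-0.317,0.293,48.2
Green-tailed Towhee,16,0.021,-0.009,0.052,75.9
Green-tailed Towhee,17,-0.155,-0.409,0.095,87.1
Green-tailed Towhee,18,-0.097,-0.27,0.075,83.3
Juniper Titmouse,9,0.002,-0.158,0.157,46.6
Juniper Titmouse,10,0.06,-0.042,0.164,84.3
Juniper Titmouse,16,0.0,-0.038,0.04,31.5
Juniper Titmouse,18,0.171,-0.034,0.382,93.8
Juniper Titmouse,33,0.067,-0.17,0.337,68.4
Juniper Titmouse,34,0.017,-0.294,0.312,53.5
Loggerhead Shrike,9,-0.015,-0.121,0.087,52.7
Loggerhead Shrike,10,0.079,0.005,0.147,96.8
Loggerhead Shrike,11,0.093,-0.076,0.258,84.2
Loggerhead Shrike,16,-0.053,-0.158,0.058,79.2
Loggerhead Shrike,17,0.061,-0.014,0.136,90.9
Loggerhead Shrike,18,0.034,-0.054,0.124,70.2
Loggerhead Shrike,33,0.027,-0.184,0.251,55.5
Sagebrush Sparrow,9,0.029,-0.092,0.164,60.6
Sagebrush Sparrow,10,0.033,-0.009,0.076,85.3
Sagebrush Sparrow,16,-0.007,-0.096,0.078,47.0
Sage Thrasher,9,-0.051,-0.134,0.026,84.4
Sage Thrasher,10,0.088,0.057,0.117,100.0
Sage Thrasher,11,0.068,-0.109,0.251,72.9
Sage Thrasher,16,0.002,-0.067,0.071,41.1
Sage Thrasher,17,0.027,-0.065,0.121,63.6
Sage Thrasher,18,-0.758,-1.572,-0.21,99.8
Sage Thrasher,33,-0.027,-0.282,0.276,58.2
Townsend's Solitaire,9,0.053,-0.104,0.229,68.6
Townsend's Solitaire,10,0.015,-0.008,0.04,68.3
Townsend's Solitaire,15,0.029,-0.262,0.288,57.4
Townsend's Solitaire,16,0.04,0.01,0.069,97.7
Townsend's Solitaire,17,-0.13,-0.205,-0.057,99.9
Townsend's Solitaire,18,-0.487,-1.016,-0.047,98.3
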