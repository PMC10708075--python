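compound,cas,threshold_mg_per_kg,odor_descriptors,source
2-nonanol,628-99-9,0.07,waxy;creamy;citrus;orange;cheese;fruity,odor-threshold compilation (water)
(E)-2-hexenal,6728-26-3,0.4286,green banana;fatty;cheesy,odor-threshold compilation (water)
nonanal,124-19-6,0.0011,waxy;rose;fresh orris;orange peel;fatty,odor-threshold compilation (water)
ethyl butanoate,105-54-4,0.0009,fruity;pineapple;brandy,odor-threshold compilation (water)
ethyl hexanoate,123-66-0,0.005,sweet;fruity;pineapple;waxy;green banana,odor-threshold compilation (water)
(3Z)-3-hexen-1-yl acetate,3681-71-8,0.031,sweet;fruity;green banana;apple;grassy,odor-threshold compilation (water)
ethyl caprylate,106-32-1,0.0193,fruity;wine;waxy;sweet;apricot;green banana;brandy;pear,odor-threshold compilation (water)
methyl salicylate,119-36-8,0.04,wintergreen;mint,odor-threshold compilation (water)
β-ocimene,3338-55-4,0.034,floral;herb;flower;sweet,odor-threshold compilation (water)
caryophyllene,87-44-5,0.064,sweet;woody;spice;clove,odor-threshold compilation (water)
α-ionone,127-41-3,0.0106,sweet;woody;floral;violet orris;fruity,odor-threshold compilation (water)
styrene,100-42-5,0.065,sweet;balsam;floral;plastic,odor-threshold compilation (water)
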