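function,category,forestland,cultivated_land,grassland,built_up_area,barren_land,water_bodies
WS,provisioning,8,0,0,0,0,2117
FP,provisioning,32,187.56,117.45,0,0,41
RM,provisioning,51.24,0,0,0,0,0
GR,provisioning,41,0,0,0,0,0
Gr,regulatory,13.68,0,7,0,0,0
Cr,regulatory,223,0,0,0,0,0
Dr,regulatory,5,0,0,0,0,0
Hr,regulatory,6,0,3,0,0,5445
EC,regulatory,245,0,29,0,0,0
BC,regulatory,0,24,23,0,0,0
WT,regulatory,136,0,87,0,0,431.5
NC,supporting,184.4,0,0,0,0,0
SF,supporting,10,0,1,0,0,0
Ha,supporting,17.3,0,0,0,0,0
Po,supporting,7.27,14,25,0,0,0
Re,recreation_culture,4.8,0,0.8,0,0,69
Cu,recreation_culture,2,0,0,0,0,0
TOTAL,,986.69,225.56,293.25,0,0,8103.5
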