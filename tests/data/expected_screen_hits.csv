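compound,percent_inhibition,capped,adjusted_p,is_hit,threshold
planted,95.02487562189056,False,0.0070010791319494725,True,50.0
c3,16.417910447761194,False,0.8274671403069341,False,50.0
c0,5.970149253731344,False,0.9962404634921722,False,50.0
c2,-1.492537313432836,False,0.9999953176294718,False,50.0
c1,-17.91044776119403,False,0.7821982549300455,False,50.0
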