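group,ir,ef,ed,bw,at
infants,0.7,365,1.5,7.5,547.5
children,0.8,365,4,15,1460
teenagers,2.0,365,13,50,4745
adults,2.5,365,40,72,14600
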