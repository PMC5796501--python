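group,statistic,derivative,feature,indices
normal,mean,0,Compactness,
normal,mean,0,FLEW,
normal,mean,0,RDF,
normal,mean,0,AMoM_LCQT,"2,7-9"
normal,sd,0,Compactness,
normal,sd,0,MFCC,"0,3-11"
normal,sd,0,LPC,"6-7"
normal,sd,0,AMoM_MFCC,"0-1,4,6"
normal,sd,0,AMoM_LCQT,"0,2,4,7-9"
normal,sd,0,AMoM_CQMFCC,"2,4,7"
normal,sd,0,sb,"1-8"
normal,sd,0,dBA,
normal,sd,0,dBC,
normal,sd,0,dB,
normal,sd,0,peak_dB,
normal,sd,0,peak_dBA,
normal,sd,0,peak_dBC,
normal,sd,1,Compactness,
normal,sd,1,FLEW,
normal,sd,1,MFCC,"0,2-3,5-12"
normal,min,0,sb,"6,8"
moderate,sd,0,FLEW,
moderate,sd,0,MFCC,"1"
moderate,sd,1,ZC,
moderate,sd,1,SF_ZC,
moderate,sd,1,MFCC,"1"
moderate,sd,1,LPC,"2,5"
severe,mean,0,SF,
severe,mean,0,MM,"0"
severe,mean,0,AMoM,"0,3,7"
severe,mean,0,AMoM_MFCC,"3"
severe,mean,0,AMoM_LCQT,"2-3,7-9"
severe,mean,0,AMoM_CQMFCC,"3,5,9"
severe,sd,0,SF,
severe,sd,0,SV,
severe,sd,0,RMS,
severe,sd,0,ZC,
severe,sd,0,SF_ZC,
severe,sd,0,SF_FFT,
severe,sd,0,LPC,"1"
severe,sd,0,MM,"0"
severe,sd,0,RDF,
severe,sd,0,AMoM,"1,3,6-8"
severe,sd,0,AMoM_MFCC,"0,1,3,4,6"
severe,sd,0,AMoM_LCQT,"0-4,6-9"
severe,sd,0,AMoM_CQMFCC,"1-4,6,7"
severe,sd,0,dBA,
severe,sd,0,dBC,
severe,sd,0,dB,
severe,sd,0,peak_dB,
severe,sd,0,peak_dBA,
severe,sd,0,peak_dBC,
severe,sd,1,SF,
severe,sd,1,SV,
severe,sd,1,RMS,
severe,sd,1,SF_FFT,
severe,sd,1,LPC,"1,7"
severe,sd,1,MM,"0,2"
severe,sd,1,RDF,
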