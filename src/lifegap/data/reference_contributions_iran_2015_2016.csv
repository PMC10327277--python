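group,cause_label,sgle_years,sgld_years
IHD,Ischemic heart disease (IHD),0.605,-0.292
treatable_preventable,Cerebrovascular diseases,0.105,-0.053
treatable_preventable,Diabetes mellitus,-0.021,0.003
treatable_preventable,Hypertensive diseases,0.060,-0.033
treatable_preventable,Other causes,0.030,-0.015
preventable,Alcohol-related deaths,0.030,-0.015
preventable,Cancers (including lung cancer),0.304,-0.120
preventable,Drug-related deaths,0.083,-0.056
preventable,Infectious diseases,0.051,-0.028
preventable,Injuries,1.128,-0.774
preventable,Other causes,-0.001,0.000
preventable,Diseases of the respiratory system,0.070,-0.028
treatable,Cancer,-0.171,0.091
treatable,Diseases of the digestive system,0.012,-0.006
treatable,Diseases of the genitourinary system,0.052,-0.029
treatable,Infectious diseases,0.010,-0.006
treatable,"Pregnancy, childbirth and perinatal period",0.104,-0.068
treatable,Other causes,0.012,-0.010
treatable,Diseases of the respiratory system,0.065,-0.031
non_avoidable,Non-avoidable,1.268,-0.398
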