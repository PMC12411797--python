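theme,beta_pd,se_pd,p_pd,beta_nd,se_nd,p_nd,more_satisfied
system login,-0.474,0.005,0.0005,2.829,0.023,0.0005,false
privacy disclosure,-0.232,0.007,0.0005,1.955,0.027,0.0005,false
storage optimization,0.220,0.005,0.0005,-2.796,0.042,0.0005,true
page design,0.223,0.005,0.0005,-2.032,0.036,0.0005,true
function provision,0.023,0.007,0.001,-0.420,0.040,0.0005,true
platform feedback,0.222,0.004,0.0005,-3.587,0.040,0.0005,true
physicians' inquiries,0.356,0.005,0.0005,-3.665,0.042,0.0005,true
menstrual management,0.209,0.006,0.0005,-0.501,0.029,0.0005,true
pregnancy guidelines,0.306,0.006,0.0005,-2.570,0.046,0.0005,true
parenting science popularization,0.238,0.006,0.0005,-1.168,0.036,0.0005,true
growth record,0.401,0.005,0.0005,-3.109,0.042,0.0005,true
maternal-infant community,0.307,0.004,0.0005,-2.416,0.028,0.0005,true
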