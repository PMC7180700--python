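tissue,eps_inf,deps1,tau1,alpha1,deps2,tau2,alpha2,deps3,tau3,alpha3,deps4,tau4,alpha4,sigma_s,source
skin,4.0,32.0,7.234e-12,0.0,1100.0,32.481e-9,0.2,0.0,159.155e-6,0.2,0.0,15.915e-3,0.2,0.0002,"Gabriel parametric compilation (dry skin)"
bone,2.5,10.0,13.263e-12,0.2,180.0,79.577e-9,0.2,5.0e3,159.155e-6,0.2,1.0e5,15.915e-3,0.0,0.02,"Gabriel parametric compilation (cortical bone)"
fat,2.5,9.0,7.958e-12,0.2,35.0,15.915e-9,0.1,3.3e4,159.155e-6,0.05,1.0e7,15.915e-3,0.01,0.035,"Gabriel parametric compilation (infiltrated fat)"
muscle,4.0,50.0,7.234e-12,0.1,7000.0,353.678e-9,0.1,1.2e6,318.310e-6,0.1,2.5e7,2.274e-3,0.1,0.2,"Gabriel parametric compilation (muscle)"
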