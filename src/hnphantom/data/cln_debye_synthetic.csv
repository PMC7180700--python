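curve,eps_inf,delta_eps,tau,sigma_s,source
cln_healthy_interior,6.0,48.0,10.0e-12,0.60,"synthetic placeholder Debye parameters; replace with user-verified lymph-node measurements"
cln_healthy_surface,3.0,8.0,13.0e-12,0.08,"synthetic placeholder Debye parameters (perinodal adipose); replace with user-verified values"
cln_metastasized_interior,7.0,55.0,10.5e-12,0.85,"synthetic placeholder Debye parameters; replace with user-verified lymph-node measurements"
cln_metastasized_surface,3.5,12.0,13.0e-12,0.15,"synthetic placeholder Debye parameters (perinodal adipose); replace with user-verified values"
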