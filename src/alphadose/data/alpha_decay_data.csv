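nuclide,member,mean_energy_MeV,yield,half_life_h
Ac-225,Ac-225,5.790,1.0000,240.0
Ac-225,Fr-221,6.301,1.0000,0.0817
Ac-225,At-217,7.067,0.9993,8.97e-6
Ac-225,Bi-213,5.870,0.0216,0.760
Ac-225,Po-213,8.376,0.9780,1.03e-9
Bi-213,Bi-213,5.870,0.0216,0.760
Bi-213,Po-213,8.376,0.9780,1.03e-9
Pb-212,Pb-212,0.0,0.0,10.6
Pb-212,Bi-212,6.051,0.3594,1.0092
Pb-212,Po-212,8.785,0.6406,8.3e-11
At-211,At-211,5.870,0.4180,7.2
At-211,Po-211,7.450,0.5820,1.43e-4
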