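species_id,role,energy_hartree,delta_e_act_printed_kjmol,provenance
tz1,tetrazine,-744.464487,,printed
tz2,tetrazine,-783.771996,,printed
tz3,tetrazine,-1087.994366,,printed
tz4,tetrazine,-1081.515706,,printed
tz5,tetrazine,-1181.953194,,printed
tz6,tetrazine,-1257.12132,,printed
tz7,tetrazine,-1332.328085,,printed
tz8,tetrazine,-760.498963,,printed
tz9,tetrazine,-566.619295,,printed
tz10,tetrazine,-641.851471,,printed
ts1,transition_state,-1057.63536,4.74,printed
ts2,transition_state,-1096.942379,6.02,reconstructed
ts3,transition_state,-1401.164459,6.78,reconstructed
ts4,transition_state,-1394.687804,1.52,reconstructed
ts5,transition_state,-1495.123556,6.08,reconstructed
ts6,transition_state,-1570.293123,2.29,reconstructed
ts7,transition_state,-1645.501028,-0.70,printed
ts8,transition_state,-1073.674144,-6.57,printed
ts9,transition_state,-879.789737,5.87,printed
ts10,transition_state,-955.023032,2.93,printed
tco,dienophile,-313.172677,,printed
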