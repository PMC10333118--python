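reserve_id,treatment_year,averted_ha,avoided_ktco2e,avoided_ktco2e_unc,scc_kusd,scc_kusd_unc,offset_kusd,offset_kusd_unc
Nawegaon-Nagzira,2013,2645,416.95,239.67,35858.08,20611.8,2418.34,1390.1
Similipal-Hadagarh,2007,1570,395.9,124.66,34047.31,10720.65,2296.21,723.02
Udanti,2009,1611,285.78,140.68,24577.02,12098.34,1657.52,815.93
Valmiki,2012,315,119.56,55.51,10282.23,4773.6,693.45,321.94
Nagarjuna Sagar-Srisailam,2007,167,19.09,10.14,1641.99,872.11,110.74,58.82
Palamau,2012,143,28.01,13.34,2409.03,1147.02,162.47,77.36
Satkosia Gorge,2007,39,8.09,3.42,695.52,294.01,46.91,19.83
Bandipur,2007,25,2.94,1.58,252.41,135.93,17.02,9.17
Biligiri Rangaswamy Temple,2011,22,3.68,1.35,316.86,115.97,21.37,7.82
Sariska,2007,14,0.68,0.45,58.21,38.36,3.93,2.59
Satpura,2007,9,1.75,0.76,150.5,64.93,10.15,4.38
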