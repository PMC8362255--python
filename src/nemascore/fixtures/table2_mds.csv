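strain,phalloidin_iband,mhca_aband,unc95_base,unc89_mline,atn1_dense_body,mds,phalloidin_iband_src,mhca_aband_src,unc95_base_src,unc89_mline_src,atn1_dense_body_src
wild_type,0,0,0,0,0,0,study,study,study,study,study
uig-1(ok884),1,1,1,1,1,5,study,study,study,study,study
pfn-3(tm1362),0,1.5,0,0,1,2.5,study,study,study,study,study
atn-1(ok84),2,0,2,0,3,7,lit,study,lit,lit,lit
alp-1(tm1137),1,0,0,0,0,1,lit,lit,study,study,lit
dyc-1(cx32),0,0,0,1,0,1,study,study,study,study,study
dim-1(ra102),2,3,1,2,1,9,study,study,study,study,study
zyx-1(gk190),0,0,0,0,0,0,study,study,study,study,study
tln-1(e259),0,1,0,0,0,1,study,study,study,study,study
unc-95(su33),3,3,3,3,3,15,lit,lit,lit,study,study
pkn-1(ok1673),0,0,0,0,0,0,lit,lit,lit,study,lit
unc-82(e1220),2,3,2,3,0,10,lit,lit,study,lit,lit
unc-89(e1460),2,3,2,3,1,11,study,unpub,study,lit,study
unc-98(sf19),1,2,0,2,1,6,study,lit,lit,lit,study
unc-22(sf21),0,0,0,0,0,0,lit,lit,lit,unpub,unpub
unc-22(e66),2,2,2,2,2,10,study,lit,lit,lit,lit
unc-54(s95),0,1,1,1,1,4,study,study,study,study,study
unc-54(s74),0,1,2,1,1,5,study,study,study,study,study
lev-11(x12),0,1,0,0,0,1,study,study,study,study,study
unc-60(r398),3,3,2,3,3,14,study,study,study,study,study
unc-94(sf20),2,1,2,1,1,7,lit,lit,study,lit,lit
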