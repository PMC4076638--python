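case_id,histotype,t_stage,n_stage,grade,er,pr,her2,ki67_percent,p53,doxo_class
BR1,IDC,pT1c,N1a,G2,70%,70%,Neg,10,Wt,Responder
BR2,IDC,pT2,pNx,G2,90%,70%,Neg,15,R280G,Responder
BR3,IDC,pT3,N1a,G2,80%,Neg,Neg,20,Wt,Non Responder
BR4,IDC,pT1c,N0,G2,80%,10%,Pos,10,Wt,Non Responder
BR5,IDC,pT2,N3a,G3,80%,90%,Neg,20,Wt,Non Responder
BR6,PC,pT2,N2a,G3,90%,5%,Neg,10,Wt,Responder
BR7,DLC,pT3,N1,G3,90%,5%,Neg,30,Wt,Responder
BR8,IDC,pT1c,N1a,G3,80%,70%,Neg,25,Wt,Responder
BR9,IDC,pT1c,N0,G2,90%,70%,Neg,20,Wt,Responder
BR10,IDC,pT2,Nx,G2,90%,95%,Neg,15,Wt,Responder
BR11,PC,pT2,N0,G1,95%,95%,Neg,10,Wt,Responder
BR12,IDC,pT1c,N0,G3,95%,60%,Neg,40,Wt,Non Responder
BR13,IDC,pT1c,N0,G2,90%,85%,Neg,15,Wt,Non Responder
BR14,ILC,pT3,N3a,G3,25%,40%,Pos,20,Wt,Non Responder
BR15,IDC,pT2,N0,G3,95%,20%,Neg,10,Wt,Responder
BR16,IDC,pT1c,N0,G2,95%,Neg,Neg,5,Wt,Non Responder
BR17,IDC,pT1c,N0,G2,95%,95%,Neg,20,Wt,Non Responder
BR18,IDC,pT3,N3,G3,Neg,Neg,Neg,45,Wt,Responder
BR19,IDC,pT2,N2,G3,90%,60%,Pos,90,Wt,Non Responder
BR20,IDC,pT2,N3a,G3,90%,2%,Pos,10,Wt,Responder
BR21,IDC,pT2,Nx,G3,90%,80%,Neg,30,Wt,Non Responder
BR22,IDC,pT1c,N0,G1,90%,90%,Neg,5,Wt,Responder
BR23,IDC,pT1c,Nx,G2,90%,40%,Neg,20,Wt,Responder
BR24,IDC,pT1c,Nx,G2,95%,95%,Neg,5,Wt,Responder
BR25,IDC,pT2,N2a,G1,90%,75%,Neg,5,K132N,Responder
BR26,IDC,pT2,N1a,G2,90%,70%,Neg,10,Wt,Non Responder
BR27,IDC,pT1c,N0,G3,90%,90%,Neg,20,Wt,Non Responder
BR28,IDC,pT2,N1a,G3,90%,10%,Neg,30,Wt,Responder
BR29,IDC,pT1c,N0,G3,90%,Neg,Neg,25,Wt,Responder
BR30,IDC,pT1c,N1a,G1,95%,95%,Neg,5,Wt,Responder
BR31,IDC,pT1c,N0,G3,Neg,Neg,Neg,40,Wt,Non Responder
BR32,IDC,pT2,N1a,G3,95%,70%,Neg,25,R248W,Non Responder
BR33,IDC,pT3,N3a,G2,90%,80%,Neg,10,Wt,Responder
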