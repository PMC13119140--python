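victim,perpetrator,cyp,age_text,observed_aucr_pediatric,aucr_adult,printed_pred_a,printed_pred_b,printed_pred_c,age_override_years
Bupivacaine,Diazepam,CYP3A4,2-10,1.70,1.25,1.25,1.21,1.72,
Carbamazepine,Erythromycin,CYP3A4,6,2.17,1.49,1.49,1.42,2.78,
Carbamazepine,Erythromycin,CYP3A4,9,3.17,1.49,1.49,1.44,2.13,
Carbamazepine,Erythromycin,CYP3A4,8,2.00,1.49,1.49,1.44,2.29,
Carbamazepine,Erythromycin,CYP3A4,9,1.63,1.49,1.49,1.45,2.13,
Carbamazepine,Valproate,CYP3A4,9,0.92,1.07,1.07,1.07,1.12,
Carbamazepine,Valproate,CYP3A4,9,0.82,1.07,1.07,1.07,1.12,
Chloroquine,Chlorpheniramine,CYP2C19,6-12,1.73,0.79,0.79,1.00,1.00,
Cyclophosphamide,Fluconazole,CYP2C19,2 m-18 y,1.29,1.79,1.79,1.00,1.00,
Cyclosporine A,Ketoconazole,CYP3A4,3,1.01,1.15,1.15,1.12,1.47,
Cyclosporine A,Norfloxacin,CYP3A4,10,1.64,1.16,1.16,1.15,1.27,
Digoxin,Amiodarone,CYP3A4,0.5-18,3.53,1.62,1.62,1.56,2.61,
Digoxin,Carvedilol,CYP3A4,2 w-7.8 y,1.90,1.16,1.16,1.13,1.45,
Efavirenz,Rifampicin,CYP2B6,3-15,0.97,0.97,0.97,1.00,0.99,
Etopside,Cyclosporine A,CYP3A4,8 m-17 y,1.47,1.25,1.25,1.23,1.48,
Etopside,Cyclosporine A,CYP3A4,4.4-20.7,1.90,1.25,1.25,1.24,1.36,
Imipramine,Carbamazepine,CYP1A2,6-16,1.06,1.06,1.06,1.00,1.01,
Lidocaine,Clonidine,CYP3A4,1-9,0.64,1.21,1.21,1.18,1.57,
Phenytoin,Chloramphenicol,CYP2C9,10-108 m,0.94,1.60,1.60,1.19,1.61,
Phenytoin,Co-trimoxazole,CYP2C9,4,1.27,1.52,1.52,1.19,1.73,
Ritonavir,Efavirenz,CYP2B6,5.7-16.3,1.27,1.09,1.09,1.01,1.01,
Theophylline,Terbutaline,CYP1A2,7-11,0.79,0.93,0.93,0.99,0.99,
Theophylline,Salbutamol,CYP1A2,19 m,0.42,0.82,0.82,0.93,0.79,
Theophylline,Salbutamol,CYP1A2,5-13,0.54,0.83,0.83,0.98,0.97,
Theophylline,Phenobarbitone,CYP1A2,8.86,0.70,0.88,0.88,0.99,0.98,
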